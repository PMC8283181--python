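keyword	group
melanoma	Melanoma
lung cancer	Lung cancer
lung carcinoma	Lung cancer
lung neoplasm	Lung cancer
non-small cell lung	Lung cancer
small cell lung	Lung cancer
nsclc	Lung cancer
bronchial	Lung cancer
lymphoma	Hematological cancer and lymphoma
hodgkin	Hematological cancer and lymphoma
leukaemia	Hematological cancer and lymphoma
leukemia	Hematological cancer and lymphoma
myeloma	Hematological cancer and lymphoma
myelodysplastic	Hematological cancer and lymphoma
gastric	Gastrointestinal cancer
stomach	Gastrointestinal cancer
colorectal	Gastrointestinal cancer
colon	Gastrointestinal cancer
rectal	Gastrointestinal cancer
oesophageal	Gastrointestinal cancer
esophageal	Gastrointestinal cancer
hepatocellular	Gastrointestinal cancer
hepatic cancer	Gastrointestinal cancer
liver cancer	Gastrointestinal cancer
pancreatic	Gastrointestinal cancer
biliary	Gastrointestinal cancer
anal	Gastrointestinal cancer
gastrointestinal	Gastrointestinal cancer
head and neck	Head and neck cancer
laryngeal	Head and neck cancer
pharyngeal	Head and neck cancer
nasopharyngeal	Head and neck cancer
oral cavity	Head and neck cancer
tongue	Head and neck cancer
breast	Breast cancer
ovarian	Tumors of female reproductive organs
ovary	Tumors of female reproductive organs
cervix	Tumors of female reproductive organs
cervical cancer	Tumors of female reproductive organs
cervical carcinoma	Tumors of female reproductive organs
uterine	Tumors of female reproductive organs
endometrial	Tumors of female reproductive organs
fallopian	Tumors of female reproductive organs
vulval	Tumors of female reproductive organs
mesothelioma	Mesothelioma
malignant neoplasm	Non-specified malignant neoplasm
neoplasm malignant	Non-specified malignant neoplasm
metastases	Non-specified malignant neoplasm
metastatic neoplasm	Non-specified malignant neoplasm
bladder	Tumors of urinary system
urothelial	Tumors of urinary system
renal	Tumors of urinary system
kidney	Tumors of urinary system
urinary	Tumors of urinary system
prostate	Tumors of urinary system
ureter	Tumors of urinary system
sarcoma	Other indications
glioblastoma	Other indications
glioma	Other indications
thymoma	Other indications
thyroid	Other indications
merkel	Other indications
squamous cell carcinoma of skin	Other indications
basal cell carcinoma	Other indications
skin cancer	Other indications
adrenal	Other indications
testicular	Other indications
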