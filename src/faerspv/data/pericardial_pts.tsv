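pt_name	meddra_code
autoimmune pericarditis	10079058
pericarditis	10034484
pericarditis adhesive	10034486
pericarditis constrictive	10034487
pleuropericarditis	10059361
cardiac tamponade	10007610
pericardial calcification	10057614
pericardial disease	10061338
pericardial effusion	10034474
pericardial fibrosis	10048724
pericardial hemorrhage	10034476
pericardial mass	10079578
pericardial rub	10049759
pneumopericardium	10048731
pericardial drainage	10034471
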