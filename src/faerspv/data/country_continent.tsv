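code	region
AD	Europe
AE	Asia
AF	Asia
AG	America
AI	America
AL	Europe
AM	Asia
AO	Africa
AR	America
AS	Oceania
AT	Europe
AU	Oceania
AW	America
AX	Europe
AZ	Asia
BA	Europe
BB	America
BD	Asia
BE	Europe
BF	Africa
BG	Europe
BH	Asia
BI	Africa
BJ	Africa
BL	America
BM	America
BN	Asia
BO	America
BQ	America
BR	America
BS	America
BT	Asia
BW	Africa
BY	Europe
BZ	America
CA	America
CD	Africa
CF	Africa
CG	Africa
CH	Europe
CI	Africa
CK	Oceania
CL	America
CM	Africa
CN	Asia
CO	America
CR	America
CU	America
CV	Africa
CW	America
CY	Asia
CZ	Europe
DE	Europe
DJ	Africa
DK	Europe
DM	America
DO	America
DZ	Africa
EC	America
EE	Europe
EG	Africa
EH	Africa
ER	Africa
ES	Europe
ET	Africa
FI	Europe
FJ	Oceania
FK	America
FM	Oceania
FO	Europe
FR	Europe
GA	Africa
GB	Europe
GD	America
GE	Asia
GF	America
GG	Europe
GH	Africa
GI	Europe
GL	America
GM	Africa
GN	Africa
GP	America
GQ	Africa
GR	Europe
GT	America
GU	Oceania
GW	Africa
GY	America
HK	Asia
HN	America
HR	Europe
HT	America
HU	Europe
ID	Asia
IE	Europe
IL	Asia
IM	Europe
IN	Asia
IQ	Asia
IR	Asia
IS	Europe
IT	Europe
JE	Europe
JM	America
JO	Asia
JP	Asia
KE	Africa
KG	Asia
KH	Asia
KI	Oceania
KM	Africa
KN	America
KP	Asia
KR	Asia
KW	Asia
KY	America
KZ	Asia
LA	Asia
LB	Asia
LC	America
LI	Europe
LK	Asia
LR	Africa
LS	Africa
LT	Europe
LU	Europe
LV	Europe
LY	Africa
MA	Africa
MC	Europe
MD	Europe
ME	Europe
MF	America
MG	Africa
MH	Oceania
MK	Europe
ML	Africa
MM	Asia
MN	Asia
MO	Asia
MP	Oceania
MQ	America
MR	Africa
MS	America
MT	Europe
MU	Africa
MV	Asia
MW	Africa
MX	America
MY	Asia
MZ	Africa
NA	Africa
NC	Oceania
NE	Africa
NF	Oceania
NG	Africa
NI	America
NL	Europe
NO	Europe
NP	Asia
NR	Oceania
NU	Oceania
NZ	Oceania
OM	Asia
PA	America
PE	America
PF	Oceania
PG	Oceania
PH	Asia
PK	Asia
PL	Europe
PM	America
PN	Oceania
PR	America
PS	Asia
PT	Europe
PW	Oceania
PY	America
QA	Asia
RE	Africa
RO	Europe
RS	Europe
RU	Europe
RW	Africa
SA	Asia
SB	Oceania
SC	Africa
SD	Africa
SE	Europe
SG	Asia
SH	Africa
SI	Europe
SJ	Europe
SK	Europe
SL	Africa
SM	Europe
SN	Africa
SO	Africa
SR	America
SS	Africa
ST	Africa
SV	America
SX	America
SY	Asia
SZ	Africa
TC	America
TD	Africa
TG	Africa
TH	Asia
TJ	Asia
TK	Oceania
TL	Asia
TM	Asia
TN	Africa
TO	Oceania
TR	Asia
TT	America
TV	Oceania
TW	Asia
TZ	Africa
UA	Europe
UG	Africa
UM	Oceania
US	America
UY	America
UZ	Asia
VA	Europe
VC	America
VE	America
VG	America
VI	America
VN	Asia
VU	Oceania
WF	Oceania
WS	Oceania
XK	Europe
YE	Asia
YT	Africa
ZA	Africa
ZM	Africa
ZW	Africa
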