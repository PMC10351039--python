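country	region
US	North America
CA	North America
MX	North America
BR	South America
AR	South America
CL	South America
CO	South America
PE	South America
VE	South America
EC	South America
UY	South America
GB	Europe
DE	Europe
FR	Europe
IT	Europe
ES	Europe
NL	Europe
BE	Europe
CH	Europe
AT	Europe
SE	Europe
NO	Europe
DK	Europe
FI	Europe
PL	Europe
PT	Europe
IE	Europe
GR	Europe
CZ	Europe
HU	Europe
RO	Europe
RU	Europe
UA	Europe
JP	Asia
CN	Asia
KR	Asia
IN	Asia
TW	Asia
TH	Asia
SG	Asia
MY	Asia
PH	Asia
VN	Asia
ID	Asia
IL	Asia
SA	Asia
TR	Asia
HK	Asia
AU	Other
NZ	Other
ZA	Other
EG	Other
NG	Other
KE	Other
MA	Other
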