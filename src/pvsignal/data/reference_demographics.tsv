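facet	level	sorafenib	sunitinib	cabozantinib	lenvatinib
sex	Females	93	38	59	5
sex	Males	250	56	176	9
sex	Missing	13	4	3	0
age	18-29	2	1	0	0
age	30-49	15	7	9	2
age	50-64	134	24	24	4
age	65-74	98	32	32	6
age	75-84	49	14	19	1
age	>=85	5	6	0	1
age	Missing	73	14	154	0
region	North America	234	44	220	9
region	South America	23	24	3	0
region	Europe	65	6	9	0
region	Asia	25	21	4	5
region	Other	6	3	0	0
region	Missing	3	0	2	0
outcome	Death	57	24	15	4
outcome	Disability	7	0	1	0
outcome	Hospitalization	182	28	40	10
outcome	Life-Threatening	6	2	1	0
outcome	Missing	104	44	181	0
indication	Renal cancer	53	51	164	3
indication	Hepatic cancer	222	0	28	8
indication	Neoplasm malignant	2	9	0	0
indication	Gastrointestinal stromal	1	7	1	0
indication	Thyroid cancer	11	1	13	0
indication	Lung neoplasm malignant	7	0	4	0
indication	Pancreatic carcinoma	7	0	1	0
indication	Other	15	5	7	3
indication	Missing	38	25	20	0
year	2006-2012	169	8	0	0
year	2013	15	0	1	0
year	2014	25	2	1	0
year	2015	39	18	3	0
year	2016	20	13	0	0
year	2017	21	14	16	0
year	2018	24	14	23	2
year	2019	17	8	30	2
year	2020	10	8	30	1
year	2021	11	6	69	3
year	2022	5	7	65	6
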