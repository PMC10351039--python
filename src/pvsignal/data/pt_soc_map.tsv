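pt	soc
Confusional state	Psychiatric disorders
Mental status changes	Psychiatric disorders
Hypersomnia	Psychiatric disorders
Feeding disorder	Psychiatric disorders
Disorientation	Psychiatric disorders
Aphonia	Psychiatric disorders
Laziness	Psychiatric disorders
Mutism	Psychiatric disorders
Thyrotoxic crisis	Psychiatric disorders
Insomnia	Psychiatric disorders
Depression	Psychiatric disorders
Anxiety	Psychiatric disorders
Hallucination	Psychiatric disorders
Agitation	Psychiatric disorders
Restlessness	Psychiatric disorders
Nervousness	Psychiatric disorders
Apathy	Psychiatric disorders
Delirium	Psychiatric disorders
Depressed mood	Psychiatric disorders
Suicidal ideation	Psychiatric disorders
Abnormal dreams	Psychiatric disorders
Bruxism	Psychiatric disorders
Emotional distress	Psychiatric disorders
Libido decreased	Psychiatric disorders
Listless	Psychiatric disorders
Mood swings	Psychiatric disorders
Nightmare	Psychiatric disorders
Panic attack	Psychiatric disorders
Sleep disorder	Psychiatric disorders
Stress	Psychiatric disorders
Delusion	Psychiatric disorders
Paranoia	Psychiatric disorders
Euphoric mood	Psychiatric disorders
Aggression	Psychiatric disorders
Irritability	Psychiatric disorders
Affect lability	Psychiatric disorders
Eating disorder	Psychiatric disorders
Initial insomnia	Psychiatric disorders
Middle insomnia	Psychiatric disorders
Psychotic disorder	Psychiatric disorders
Diarrhoea	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Abdominal pain	Gastrointestinal disorders
Stomatitis	Gastrointestinal disorders
Hypertension	Vascular disorders
Hypotension	Vascular disorders
Palmar-plantar erythrodysaesthesia syndrome	Skin and subcutaneous tissue disorders
Rash	Skin and subcutaneous tissue disorders
Alopecia	Skin and subcutaneous tissue disorders
Fatigue	General disorders and administration site conditions
Asthenia	General disorders and administration site conditions
Pyrexia	General disorders and administration site conditions
Oedema peripheral	General disorders and administration site conditions
Decreased appetite	Metabolism and nutrition disorders
Dehydration	Metabolism and nutrition disorders
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Dysgeusia	Nervous system disorders
Proteinuria	Renal and urinary disorders
Acute kidney injury	Renal and urinary disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
Cough	Respiratory, thoracic and mediastinal disorders
Hypothyroidism	Endocrine disorders
Blood pressure increased	Investigations
Weight decreased	Investigations
Arthralgia	Musculoskeletal and connective tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
Anaemia	Blood and lymphatic system disorders
Thrombocytopenia	Blood and lymphatic system disorders
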