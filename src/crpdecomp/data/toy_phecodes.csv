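phecode,icd10,exclude_low,exclude_high,category,description
10.0,A15,10.0,10.99,Infectious diseases,Tuberculosis
10.0,A16,10.0,10.99,Infectious diseases,Tuberculosis
71.0,B20,71.0,71.99,Infectious diseases,Human immunodeficiency virus (HIV) disease
71.0,B24,71.0,71.99,Infectious diseases,Human immunodeficiency virus (HIV) disease
250.1,E10,249.0,250.99,Endocrine/metabolic,Type 1 diabetes
250.2,E11,249.0,250.99,Endocrine/metabolic,Type 2 diabetes
251.1,E16,249.0,251.99,Endocrine/metabolic,Hypoglycemia
242.2,E05,242.0,242.99,Endocrine/metabolic,Toxic multinodular goiter
295.1,F20,295.0,295.99,Mental disorders,Schizophrenia
401.1,I10,401.0,401.99,Circulatory system,Essential hypertension
401.21,I11,401.0,401.99,Circulatory system,Hypertensive heart disease
585.3,N18,580.0,589.99,Genitourinary,Chronic renal failure (CKD)
580.2,N04,580.0,589.99,Genitourinary,Nephrotic syndrome without mention of glomerulonephritis
697.0,D86,697.0,697.99,Dermatologic,Sarcoidosis
695.42,M32,695.4,695.49,Dermatologic,Systemic lupus erythematosus
282.5,D57,282.0,282.99,Hematopoietic,Sickle cell anemia
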