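# CKiD-U25 eGFR coefficients, transcribed from Pierce CB, Munoz A, Ng DK,
# Warady BA, Furth SL, Schwartz GJ. Age- and sex-dependent clinical equations
# to estimate glomerular filtration rates in children and young adults with
# chronic kidney disease. Kidney Int 2021;99(4):948-956.
# K(age) = k * growth ** (age - pivot_age); age bands are [age_low, age_high).
# creatinine arm: eGFR = K * height_m / Scr(mg/dl)
# cystatin arm:   eGFR = K / cystatin_C(mg/L)
sex,age_low,age_high,analyte,k,growth,pivot_age
male,1,12,creatinine,39.0,1.008,12
male,12,18,creatinine,39.0,1.045,12
male,18,25,creatinine,50.8,1.0,0
female,1,12,creatinine,36.1,1.008,12
female,12,18,creatinine,36.1,1.023,12
female,18,25,creatinine,41.4,1.0,0
male,1,15,cystatin,87.2,1.011,15
male,15,18,cystatin,87.2,0.960,15
male,18,25,cystatin,77.1,1.0,0
female,1,12,cystatin,79.9,1.004,12
female,12,18,cystatin,79.9,0.974,12
female,18,25,cystatin,68.3,1.0,0
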