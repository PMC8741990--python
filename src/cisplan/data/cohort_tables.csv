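patient_id,histology,dose_mg,n_injections,volume_cm3,v_response_printed,prediction_printed,outcome
ADN-1,ADN,40,4,152.63,18,0,1
ADN-2,ADN,40,4,0.95,100,1,1
ADN-3,ADN,40,4,4.57,100,1,1
ADN-4,ADN,40,4,3.35,100,1,1
ADN-5,ADN,40,4,38.04,57,0,0
ADN-6,ADN,40,4,6.57,99,1,1
ADN-7,ADN,40,4,66.30,32,0,0
ADN-8,ADN,40,4,9.44,96,1,1
ADN-9,ADN,40,4,13.41,77,1,1
ADN-10,ADN,40,4,6.52,98,1,1
ADN-11,ADN,40,4,3.27,100,1,1
ADN-12,ADN,40,5,1.43,100,1,1
ADN-13,ADN,10,5,2.10,99,1,1
ADN-14,ADN,30,5,27.77,72,1,0
ADN-15,ADN,40,5,229.95,14,0,1
SQC-1,SQC,40,4,59.71,38,0,0
SQC-2,SQC,40,4,5.75,85,1,1
SQC-3,SQC,40,4,1.85,100,1,0
SQC-4,SQC,40,4,38.49,56,0,1
SQC-5,SQC,40,4,14.89,91,1,1
SQC-6,SQC,20,2,7.29,82,1,1
SQC-7,SQC,40,4,27.04,71,1,1
SQC-8,SQC,40,4,1.76,100,1,0
SQC-9,SQC,40,4,2.60,95,1,0
SQC-10,SQC,40,4,1.12,100,1,1
SQC-11,SQC,10,5,28.59,58,0,1
SQC-12,SQC,10,5,4.74,97,1,1
SQC-13,SQC,10,5,2.73,100,1,1
SQC-14,SQC,40,5,15.02,95,1,0
SQC-15,SQC,10,5,1.67,100,1,1
SQC-16,SQC,40,5,31.59,73,1,1
LCC-1,LCC,40,4,1.53,100,1,1
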