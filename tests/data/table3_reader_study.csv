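reader,modality,truth,called_real,called_synthetic
radiologist_1,DWI_b0,real,21,4
radiologist_1,DWI_b0,synthetic,20,5
radiologist_1,ADC,real,18,7
radiologist_1,ADC,synthetic,21,4
radiologist_1,DWI_b1000,real,21,4
radiologist_1,DWI_b1000,synthetic,20,5
radiologist_2,DWI_b0,real,22,3
radiologist_2,DWI_b0,synthetic,20,5
radiologist_2,ADC,real,21,4
radiologist_2,ADC,synthetic,19,6
radiologist_2,DWI_b1000,real,21,4
radiologist_2,DWI_b1000,synthetic,21,4
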