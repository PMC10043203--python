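feature_id,name,panel,precision
f0,Age,age,0
f1,Basophils,blood_routine,2
f2,Basophil ratio,blood_routine,2
f3,Eosinophils,blood_routine,2
f4,Eosinophil ratio,blood_routine,2
f5,Hematocrit,blood_routine,2
f6,Hemoglobin,blood_routine,2
f7,Large platelet ratio,blood_routine,2
f8,Lymphocyte count,blood_routine,2
f9,Lymphocyte ratio,blood_routine,2
f10,Mean corpuscular hemoglobin,blood_routine,2
f11,Mean corpuscular hemoglobin concentration,blood_routine,2
f12,Mean corpuscular volume,blood_routine,2
f13,Mean platelet volume,blood_routine,2
f14,Monocyte count,blood_routine,2
f15,Monocyte ratio,blood_routine,2
f16,Neutrophil count,blood_routine,2
f17,Neutrophil ratio,blood_routine,2
f18,Platelet,blood_routine,2
f19,Platelet crit,blood_routine,2
f20,Platelet distribution width,blood_routine,2
f21,Alanine aminotransferase,liver_kidney,2
f22,Albumin,liver_kidney,2
f23,Albumin to globulin ratio,liver_kidney,2
f24,Alkaline phosphatase,liver_kidney,2
f25,Aspartate aminotransferase,liver_kidney,2
f26,Calcium,liver_kidney,2
f27,Chloride,liver_kidney,2
f28,Creatine isoenzyme,liver_kidney,2
f29,Creatine kinase,liver_kidney,2
f30,C-reactive protein,liver_kidney,2
f31,Creatinine,liver_kidney,2
f32,Direct bilirubin,liver_kidney,2
f33,Globulin,liver_kidney,2
f34,Glutamyl transpeptidase,liver_kidney,2
f35,Indirect bilirubin,liver_kidney,2
f36,Lactate dehydrogenase,liver_kidney,2
f37,Myoglobin,liver_kidney,2
f38,Potassium,liver_kidney,2
f39,Prealbumin,liver_kidney,2
f40,Retinol-binding protein,liver_kidney,2
f41,Sodium,liver_kidney,2
f42,Total bilirubin,liver_kidney,2
f43,Troponin I,liver_kidney,2
f44,Total protein,liver_kidney,2
f45,Transaminase ratio,liver_kidney,2
f46,Urea,liver_kidney,2
f47,Uric acid,liver_kidney,2
f48,Urea: creatinine,liver_kidney,2
f49,5'-nucleotidase,liver_kidney,2
f50,Beta-2 microglobulin,liver_kidney,2
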