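table,type,tp,fp,fn,precision,recall,f1
entities_iaa,ischaemic stroke,453,9,2,98.05,99.56,98.80
entities_iaa,haemorrhagic stroke,264,20,3,92.96,98.88,95.83
entities_iaa,stroke (unknown type),25,0,1,100.00,96.15,98.04
entities_iaa,tumour:meningioma,8,0,0,100.00,100.00,100.00
entities_iaa,tumour:metastasis,12,0,0,100.00,100.00,100.00
entities_iaa,tumour,165,2,1,98.80,99.40,99.10
entities_iaa,subdural haematoma,109,32,0,77.30,100.00,87.20
entities_iaa,small vessel disease,269,15,7,94.72,97.46,96.07
entities_iaa,atrophy,147,14,6,91.30,96.08,93.63
entities_iaa,microhaemorrhage,10,0,0,100.00,100.00,100.00
entities_iaa,subarachnoid haemorrhage,9,3,1,75.00,90.00,81.82
entities_iaa,haemorrhagic transformation,2,2,0,50.00,100.00,66.67
entities_iaa,time:old,314,9,7,97.21,97.82,97.52
entities_iaa,time:recent,354,0,0,100.00,100.00,100.00
entities_iaa,loc:cortical,410,5,2,98.80,99.51,99.15
entities_iaa,loc:deep,321,17,22,94.97,93.59,94.27
entities_iaa,TOTAL,2872,128,52,95.73,98.22,96.96
relations_iaa,mod-loc,235,17,25,93.25,90.38,91.80
relations_iaa,mod-time,421,12,3,97.23,99.29,98.25
relations_iaa,TOTAL,656,29,28,95.77,95.91,95.84
labels_iaa,"Ischaemic stroke, deep, recent",4,0,0,100.00,100.00,100.00
labels_iaa,"Ischaemic stroke, deep, old",81,4,4,95.29,95.29,95.29
labels_iaa,"Ischaemic stroke, cortical, recent",13,3,1,81.25,92.86,86.67
labels_iaa,"Ischaemic stroke, cortical, old",58,6,3,90.62,95.08,92.80
labels_iaa,"Ischaemic stroke, underspecified",6,6,6,50.00,50.00,50.00
labels_iaa,"Haemorrhagic stroke, deep, recent",2,1,0,66.67,100.00,80.00
labels_iaa,"Haemorrhagic stroke, deep, old",4,0,0,100.00,100.00,100.00
labels_iaa,"Haemorrhagic stroke, lobar, recent",4,0,0,100.00,100.00,100.00
labels_iaa,"Haemorrhagic stroke, lobar, old",3,0,0,100.00,100.00,100.00
labels_iaa,"Haemorrhagic stroke, underspecified",9,0,1,100.00,90.00,94.74
labels_iaa,"Stroke, underspecified",14,1,1,93.33,93.33,93.33
labels_iaa,"Tumour, meningioma",4,0,0,100.00,100.00,100.00
labels_iaa,"Tumour, metastasis",0,0,0,NaN,NaN,NaN
labels_iaa,"Tumour, glioma",0,0,0,NaN,NaN,NaN
labels_iaa,"Tumour, other",2,3,1,40.00,66.67,50.00
labels_iaa,Small vessel disease,158,3,1,98.14,99.37,98.75
labels_iaa,Atrophy,119,9,3,92.97,97.54,95.20
labels_iaa,Subdural haematoma,6,0,0,100.00,100.00,100.00
labels_iaa,"Subarachnoid haemorrhage, aneurysmal",0,0,0,NaN,NaN,NaN
labels_iaa,"Subarachnoid haemorrhage, other",5,2,1,71.43,83.33,76.92
labels_iaa,"Microbleed, deep",1,1,0,50.00,100.00,66.67
labels_iaa,"Microbleed, lobar",1,0,0,100.00,100.00,100.00
labels_iaa,"Microbleed, underspecified",0,0,1,NaN,0.00,NaN
labels_iaa,Haemorrhagic transformation,1,1,0,50.00,100.00,66.67
labels_iaa,TOTAL,495,40,23,92.52,95.56,94.02
labels_system,"Ischaemic stroke, deep, recent",4,1,0,80.00,100.00,88.89
labels_system,"Ischaemic stroke, deep, old",81,5,4,94.19,95.29,94.74
labels_system,"Ischaemic stroke, cortical, recent",14,1,2,93.33,87.50,90.32
labels_system,"Ischaemic stroke, cortical, old",56,5,8,91.80,87.50,89.60
labels_system,"Ischaemic stroke, underspecified",6,8,6,42.86,50.00,46.15
labels_system,"Haemorrhagic stroke, deep, recent",3,0,0,100.00,100.00,100.00
labels_system,"Haemorrhagic stroke, deep, old",4,1,0,80.00,100.00,88.89
labels_system,"Haemorrhagic stroke, lobar, recent",4,1,0,80.00,100.00,88.89
labels_system,"Haemorrhagic stroke, lobar, old",3,1,0,75.00,100.00,85.71
labels_system,"Haemorrhagic stroke, underspecified",9,3,0,75.00,100.00,85.71
labels_system,"Stroke, underspecified",13,1,2,92.86,86.67,89.66
labels_system,"Tumour, meningioma",4,1,0,80.00,100.00,88.89
labels_system,"Tumour, metastasis",0,3,0,0.00,NaN,NaN
labels_system,"Tumour, glioma",0,0,0,NaN,NaN,NaN
labels_system,"Tumour, other",4,2,1,66.67,80.00,72.73
labels_system,Small vessel disease,158,0,3,100.00,98.14,99.06
labels_system,Atrophy,120,3,8,97.56,93.75,95.62
labels_system,Subdural haematoma,5,0,1,100.00,83.33,90.91
labels_system,"Subarachnoid haemorrhage, aneurysmal",0,0,0,NaN,NaN,NaN
labels_system,"Subarachnoid haemorrhage, other",4,1,3,80.00,57.14,66.67
labels_system,"Microbleed, deep",1,0,1,100.00,50.00,66.67
labels_system,"Microbleed, lobar",1,0,0,100.00,100.00,100.00
labels_system,"Microbleed, underspecified",0,2,0,0.00,NaN,NaN
labels_system,Haemorrhagic transformation,1,0,1,100.00,50.00,66.67
labels_system,TOTAL,495,39,40,92.70,92.52,92.61
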