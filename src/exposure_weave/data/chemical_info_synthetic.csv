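chemical_id,name,molecular_weight,class_label,lod_ng_g,loq_ng_g
chem00,naphthalene,128.17,PAH,2.1,6.3
chem01,2-methylnaphthalene,142.20,PAH,1.8,5.4
chem02,"1,6-dimethylnaphthalene",156.22,PAH,1.5,4.5
chem03,fluorene,166.22,PAH,1.2,3.6
chem04,phenanthrene,178.23,PAH,1.0,3.0
chem05,anthracene,178.23,PAH,1.1,3.3
chem06,fluoranthene,202.25,PAH,0.9,2.7
chem07,pyrene,202.25,PAH,0.9,2.7
chem08,retene,234.38,PAH,1.4,4.2
chem09,9-fluorenone,180.20,OPAH,2.6,7.8
chem10,"9,10-anthraquinone",208.21,OPAH,3.1,9.3
chem11,n-nonane,128.26,alkane,4.4,13.2
chem12,n-dodecane,170.33,alkane,3.9,11.7
chem13,n-tetradecane,198.39,alkane,3.2,9.6
chem14,n-heptadecane,240.47,alkane,2.8,8.4
chem15,n-octadecane,254.49,alkane,2.7,8.1
chem16,n-eicosane,282.55,alkane,2.5,7.5
chem17,ethylbenzene,106.17,VOC,5.3,15.9
chem18,o-xylene,106.17,VOC,5.1,15.3
chem19,"m,p-xylene",106.17,VOC,5.2,15.6
chem20,"1,2,4-trimethylbenzene",120.19,VOC,4.7,14.1
chem21,tributyl phosphate,266.32,OPE,1.9,5.7
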