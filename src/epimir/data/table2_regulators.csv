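symbol,aliases,categories,expression_bin,diseases,n_total,n_up,n_down
Dnmt1,,DNA methyltransferase,low,congestive heart failure|cardiomyopathy,4,0,4
Dnmt3a,,DNA methyltransferase,low,congenital heart disease,3,0,3
Alkbh4,,DNA demethylase,low,,4,2,2
Brpf1,,histone acetyltransferase,low,,1,1,0
Clock,Kat13d,histone acetyltransferase,medium,cardiomyopathy,17,7,10
Crebbp,Kat3a,histone acetyltransferase,medium,cardiomyopathy,2,1,1
Ing3,,histone acetyltransferase,low,,3,2,1
Ing4,,histone acetyltransferase,medium,,1,0,1
Jade1,,histone acetyltransferase,medium,,1,0,1
Jade2,,histone acetyltransferase,low,,1,0,1
Kat5,,histone acetyltransferase,medium,,1,0,1
Kat6a,,histone acetyltransferase,medium,congenital heart disease,5,2,3
Kat7,,histone acetyltransferase,medium,,2,0,2
Naa40,Nat11,histone acetyltransferase,medium,,2,1,1
Naa50,Nat5|Nat13|Mak3,histone acetyltransferase,medium,,7,4,3
Naa60,Hat4,histone acetyltransferase,medium,,1,0,1
Tada2a,,histone acetyltransferase,low,,1,1,0
Taf1,Kat4,histone acetyltransferase,low,congenital heart disease,1,0,1
Atxn3,,histone deacetylase,low,,3,2,1
Hdac1,,histone deacetylase,medium,congestive heart failure|cardiomyopathy,1,0,1
Hdac4,,histone deacetylase,low,congestive heart failure,1,1,0
Mier1,,histone deacetylase,medium,,6,1,5
Mier2,,histone deacetylase,low,,1,0,1
Mier3,,histone deacetylase,low,,3,1,2
Mta2,,histone deacetylase,medium,,1,1,0
Sirt2,,histone deacetylase,medium,,1,1,0
Sirt3,,histone deacetylase,medium,congestive heart failure,1,1,0
Sirt5,,histone deacetylase,medium,,1,0,1
Ash1l,Kmt2h,histone methyltransferase,medium,,4,2,2
Carm1,,histone methyltransferase,medium,,1,0,1
Dot1l,Kmt4,histone methyltransferase,low,cardiomyopathy,4,3,1
Ehmt2,Kmt1c,histone methyltransferase,medium,,1,1,0
Ezh1,Kmt6b,histone methyltransferase,medium,,3,1,2
Ezh2,Kmt6a,histone methyltransferase,low,congestive heart failure,3,2,1
Kmt2e,,histone methyltransferase,medium,,1,1,0
Kmt5b,,histone methyltransferase,medium,,4,3,1
Kmt5c,,histone methyltransferase,medium,,1,1,0
Mecom,Kmt8e,histone methyltransferase,low,,2,1,1
Nsd1,Kmt3b,histone methyltransferase,medium,congenital heart disease,1,1,0
Nsd2,Kmt3g,histone methyltransferase,low,cardiomyopathy,2,1,1
Nsd3,Kmt3f,histone methyltransferase,low,,1,0,1
Ntmt1,,histone methyltransferase,medium,,1,0,1
Prdm2,Kmt8|Kmt8a,histone methyltransferase,low,,1,0,1
Prmt1,,histone methyltransferase,medium,,1,1,0
Setd2,Kmt3a,histone methyltransferase,medium,,2,1,1
Setd5,,histone methyltransferase,medium,cardiomyopathy,8,5,3
Setd7,Kmt7,histone methyltransferase,medium,,1,1,0
Smyd2,Kmt3c,histone methyltransferase,medium,,1,1,0
Smyd5,,histone methyltransferase,low,,1,0,1
Wdr5,,histone methyltransferase,medium,congenital heart disease,1,0,1
Hr,,histone demethylase,low,congenital heart disease,1,0,1
Jmjd1c,Kdm3c,histone demethylase,medium,,3,2,1
Jmjd6,,histone demethylase,medium,,1,1,0
Kdm2a,,histone demethylase,medium,congestive heart failure,2,1,1
Kdm2b,,histone demethylase,low,,3,2,1
Kdm3a,,histone demethylase,medium,,4,1,3
Kdm4a,,histone demethylase,medium,cardiomegaly,4,2,2
Kdm5a,,histone demethylase,medium,,6,4,2
Kdm5b,,histone demethylase,low,myocardial infarction,2,1,1
Kdm6b,,histone demethylase,medium,,1,0,1
Phf2,Kdm7c,histone demethylase,medium,,1,0,1
Phf8,Kdm7b,histone demethylase,low,,2,0,2
Rsbn1,Kdm9,histone demethylase,low,,7,3,4
Dtx3l,,histone ubiquitin ligase,low,,2,1,1
Pcgf5,,histone ubiquitin ligase,medium,,3,3,0
Rnf168,,histone ubiquitin ligase,low,,2,1,1
Bap1,,histone deubiquitinase,medium,cardiomyopathy,1,0,1
Usp3,,histone deubiquitinase,low,cardiomyopathy,1,1,0
Usp36,,histone deubiquitinase,low,,3,1,2
Usp49,,histone deubiquitinase,low,,6,2,4
Aurkb,,histone kinase,low,,1,1,0
Baz1b,,histone kinase,medium,williams-beuren syndrome,1,0,1
Bub1,,histone kinase,low,,1,1,0
Ccnb1,,histone kinase,low,,1,0,1
Cdk2,,histone kinase,low,,1,0,1
Chek1,,histone kinase,low,,2,1,1
Dcaf1,,histone kinase,low,,3,2,1
Prkaa1,Ampka1,histone kinase,low,,1,0,1
Prkca,Pkca|Pkcaalpha,histone kinase,low,congestive heart failure|cardiomyopathy,6,4,2
Prkcb,Pkcb|Pkcbeta,histone kinase,low,congestive heart failure|cardiomyopathy,6,3,3
Rps6ka5,Msk1,histone kinase,low,,3,0,3
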