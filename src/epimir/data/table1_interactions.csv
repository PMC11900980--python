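mirna,direction,gene,cumulative_score,high_confidence,mirna_previously_reported
rno-let-7b-3p,1,Dcaf1,1.95,1,0
rno-let-7b-3p,1,Kdm2b,1.91,1,0
rno-let-7b-3p,1,Pcgf5,1.89,1,0
rno-let-7b-3p,1,Clock,1.59,0,0
rno-let-7b-3p,1,Dot1l,1.48,0,0
rno-let-7c-5p,1,Kdm3a,1.73,1,1
rno-let-7c-5p,1,Mier1,1.73,1,1
rno-let-7c-5p,1,Alkbh4,1.71,0,1
rno-let-7f-1-3p,1,Kdm2b,1.91,1,0
rno-let-7f-1-3p,1,Pcgf5,1.81,1,0
rno-miR-10b-5p,1,Kdm5b,1.61,0,0
rno-miR-126a-5p,1,Setd5,1.54,0,1
rno-miR-132-3p,1,Setd5,1.87,1,1
rno-miR-132-3p,1,Kdm5a,1.80,1,1
rno-miR-132-3p,1,Setd7,1.46,0,1
rno-miR-133a-3p,1,Dot1l,1.63,0,1
rno-miR-133b-3p,1,Dot1l,1.71,0,1
rno-miR-146b-3p,1,Setd5,1.86,1,0
rno-miR-146b-3p,1,Prkca,1.61,0,0
rno-miR-146b-3p,1,Kmt5c,1.55,0,0
rno-miR-148b-5p,1,Kdm5a,1.78,0,0
rno-miR-148b-5p,1,Naa50,1.64,0,0
rno-miR-18a-3p,1,Tada2a,1.69,0,0
rno-miR-18a-3p,1,Smyd2,1.51,0,0
rno-miR-217-3p,1,Mecom,1.70,0,1
rno-miR-217-3p,1,Prkcb,1.66,0,1
rno-miR-217-3p,1,Rnf168,1.58,0,1
rno-miR-217-3p,1,Kdm5a,1.57,0,1
rno-miR-26a-5p,1,Usp3,1.92,1,1
rno-miR-26a-5p,1,Ezh2,1.78,1,1
rno-miR-26a-5p,1,Ing3,1.62,0,1
rno-miR-26a-5p,1,Nsd2,1.50,0,1
rno-miR-299b-5p,1,Bub1,1.79,1,0
rno-miR-299b-5p,1,Hdac4,1.71,0,0
rno-miR-299b-5p,1,Kdm4a,1.70,0,0
rno-miR-299b-5p,1,Rsbn1,1.69,0,0
rno-miR-299b-5p,1,Clock,1.55,0,0
rno-miR-322-5p,1,Ash1l,1.92,1,0
rno-miR-322-5p,1,Clock,1.85,1,0
rno-miR-322-5p,1,Usp49,1.68,0,0
rno-miR-322-5p,1,Chek1,1.60,0,0
rno-miR-322-5p,1,Rsbn1,1.56,0,0
rno-miR-324-3p,1,Prmt1,1.65,0,1
rno-miR-330-5p,1,Sirt2,1.77,0,0
rno-miR-330-5p,1,Ehmt2,1.71,0,0
rno-miR-330-5p,1,Jmjd6,1.70,0,0
rno-miR-330-5p,1,Prkca,1.54,0,0
rno-miR-343,1,Nsd1,1.89,1,0
rno-miR-343,1,Kdm2a,1.80,1,0
rno-miR-343,1,Clock,1.64,0,0
rno-miR-3547,1,Naa40,1.80,1,0
rno-miR-3547,1,Aurkb,1.76,0,0
rno-miR-3572,1,Jmjd1c,1.86,1,0
rno-miR-3572,1,Dcaf1,1.78,0,0
rno-miR-3572,1,Naa50,1.76,0,0
rno-miR-3572,1,Kat6a,1.74,0,0
rno-miR-3572,1,Kmt5b,1.66,0,0
rno-miR-3583-3p,1,Prkcb,1.93,1,0
rno-miR-3583-3p,1,Kmt5b,1.65,0,0
rno-miR-3583-3p,1,Ing3,1.60,0,0
rno-miR-3583-3p,1,Clock,1.53,0,0
rno-miR-3590-5p,1,Naa50,1.69,0,0
rno-miR-3590-5p,1,Dtx3l,1.67,0,0
rno-miR-3593-3p,1,Ash1l,1.70,0,0
rno-miR-375-5p,1,Pcgf5,1.69,0,0
rno-miR-376c-5p,1,Kat6a,1.77,0,0
rno-miR-376c-5p,1,Setd2,1.74,0,0
rno-miR-410-5p,1,Setd5,1.74,0,0
rno-miR-410-5p,1,Prkca,1.73,0,0
rno-miR-434-5p,1,Atxn3,1.68,0,0
rno-miR-484,1,Prkcb,1.77,0,0
rno-miR-484,1,Clock,1.73,0,0
rno-miR-484,1,Ezh1,1.54,0,0
rno-miR-674-3p,1,Alkbh4,1.88,1,0
rno-miR-674-3p,1,Prkca,1.78,0,0
rno-miR-674-3p,1,Usp49,1.61,0,0
rno-miR-741-3p,1,Crebbp,1.68,0,0
rno-miR-741-3p,1,Kdm5a,1.56,0,0
rno-miR-741-3p,1,Kmt2e,1.53,0,0
rno-miR-764-5p,1,Naa50,1.71,0,0
rno-miR-874-5p,1,Sirt3,1.81,1,0
rno-miR-874-5p,1,Brpf1,1.79,0,0
rno-miR-874-5p,1,Mta2,1.75,0,0
rno-miR-874-5p,1,Kdm4a,1.66,0,0
rno-miR-881-3p,1,Clock,1.82,1,0
rno-miR-881-3p,1,Jmjd1c,1.60,0,0
rno-miR-92b-3p,1,Usp36,1.94,1,1
rno-miR-92b-3p,1,Ezh2,1.90,1,1
rno-miR-92b-3p,1,Kmt5b,1.89,1,1
rno-miR-92b-3p,1,Atxn3,1.88,1,1
rno-miR-92b-3p,1,Rsbn1,1.85,1,1
rno-miR-92b-3p,1,Mier3,1.75,1,1
rno-miR-92b-3p,1,Setd5,1.74,0,1
let-7d-5p,-1,Alkbh4,1.79,0,1
let-7d-5p,-1,Mier1,1.79,0,1
let-7d-5p,-1,Kdm3a,1.71,0,1
rno-miR-100-5p,-1,Ntmt1,1.60,0,0
rno-miR-1193-3p,-1,Naa50,1.69,0,0
rno-miR-140-3p,-1,Kmt5b,1.76,0,0
rno-miR-140-3p,-1,Usp49,1.68,0,0
rno-miR-140-3p,-1,Kdm5a,1.66,0,0
rno-miR-140-3p,-1,Ing4,1.63,0,0
rno-miR-140-3p,-1,Mier3,1.62,0,0
rno-miR-142-3p,-1,Clock,1.67,0,0
rno-miR-142-3p,-1,Ash1l,1.64,0,0
rno-miR-148b-3p,-1,Nsd2,1.79,1,0
rno-miR-148b-3p,-1,Kat7,1.76,0,0
rno-miR-148b-3p,-1,Mier1,1.68,0,0
rno-miR-148b-3p,-1,Dnmt1,1.65,0,0
rno-miR-183-3p,-1,Kdm5b,1.91,1,0
rno-miR-183-3p,-1,Cdk2,1.65,0,0
rno-miR-183-5p,-1,Kdm2b,1.73,0,0
rno-miR-183-5p,-1,Prkca,1.71,0,0
rno-miR-183-5p,-1,Baz1b,1.61,0,0
rno-miR-1843a-5p,-1,Phf8,1.81,1,0
rno-miR-1843a-5p,-1,Clock,1.61,0,0
rno-miR-1843a-5p,-1,Usp36,1.59,0,0
rno-miR-1843a-5p,-1,Naa60,1.51,0,0
rno-miR-186-5p,-1,Rps6ka5,1.78,0,0
rno-miR-186-5p,-1,Mier1,1.77,0,0
rno-miR-186-5p,-1,Dcaf1,1.67,0,0
rno-miR-193a-3p,-1,Kat5,1.66,0,0
rno-miR-194-5p,-1,Setd5,1.81,1,0
rno-miR-194-5p,-1,Rsbn1,1.79,0,0
rno-miR-194-5p,-1,Naa50,1.65,0,0
rno-miR-194-5p,-1,Clock,1.63,0,0
rno-miR-195-5p,-1,Clock,1.85,1,1
rno-miR-195-5p,-1,Rsbn1,1.66,0,1
rno-miR-195-5p,-1,Usp49,1.62,0,1
rno-miR-195-5p,-1,Ezh1,1.61,0,1
rno-miR-195-5p,-1,Chek1,1.54,0,1
rno-miR-199a-3p,-1,Kdm3a,1.87,1,1
rno-miR-199a-3p,-1,Dnmt3a,1.57,0,1
rno-miR-19b-3p,-1,Mier3,1.75,1,0
rno-miR-19b-3p,-1,Mier1,1.72,0,0
rno-miR-19b-3p,-1,Mecom,1.64,0,0
rno-miR-19b-3p,-1,Rps6ka5,1.61,0,0
rno-miR-204-3p,-1,Phf2,1.74,1,0
rno-miR-21-3p,-1,Naa50,1.89,1,1
rno-miR-21-3p,-1,Setd2,1.76,1,1
rno-miR-21-3p,-1,Ing3,1.69,0,1
rno-miR-21-3p,-1,Setd5,1.68,0,1
rno-miR-22-3p,-1,Phf8,1.92,1,0
rno-miR-22-3p,-1,Rsbn1,1.81,1,0
rno-miR-22-3p,-1,Usp36,1.67,0,0
rno-miR-22-3p,-1,Kdm6b,1.64,0,0
rno-miR-22-3p,-1,Kat6a,1.62,0,0
rno-miR-297,-1,Clock,1.68,0,0
rno-miR-29c-3p,-1,Clock,1.89,1,1
rno-miR-29c-3p,-1,Dnmt3a,1.88,1,1
rno-miR-29c-3p,-1,Dot1l,1.85,1,1
rno-miR-29c-3p,-1,Naa40,1.85,1,1
rno-miR-29c-3p,-1,Kdm2a,1.76,0,1
rno-miR-300-5p,-1,Dnmt1,1.59,0,0
rno-miR-300-5p,-1,Kdm3a,1.58,0,0
rno-miR-300-5p,-1,Taf1,1.55,0,0
rno-miR-300-5p,-1,Ccnb1,1.55,0,0
rno-miR-30e-3p,-1,Atxn3,1.86,1,1
rno-miR-30e-3p,-1,Prkaa1,1.75,0,1
rno-miR-30e-3p,-1,Clock,1.54,0,1
rno-miR-30e-3p,-1,Kdm5a,1.51,0,1
rno-miR-31a-5p,-1,Wdr5,1.88,1,0
rno-miR-31a-5p,-1,Rsbn1,1.79,1,0
rno-miR-31a-5p,-1,Nsd3,1.74,1,0
rno-miR-31a-5p,-1,Bap1,1.69,0,0
rno-miR-31a-5p,-1,Clock,1.65,0,0
rno-miR-31a-5p,-1,Ash1l,1.62,0,0
rno-miR-342-3p,-1,Kdm4a,1.76,0,1
rno-miR-34c-5p,-1,Jmjd1c,1.77,0,0
rno-miR-34c-5p,-1,Prkcb,1.74,0,0
rno-miR-34c-5p,-1,Hr,1.65,0,0
rno-miR-34c-5p,-1,Hdac1,1.61,0,0
rno-miR-34c-5p,-1,Jade2,1.45,0,0
rno-miR-3559-5p,-1,Prkcb,1.88,1,0
rno-miR-3559-5p,-1,Mier1,1.87,0,0
rno-miR-3559-5p,-1,Rps6ka5,1.66,0,0
rno-miR-421-3p,-1,Kat6a,1.51,0,0
rno-miR-466b-5p,-1,Dnmt1,1.81,1,0
rno-miR-466b-5p,-1,Crebbp,1.62,0,0
rno-miR-496-5p,-1,Setd5,1.74,0,0
rno-miR-496-5p,-1,Prkca,1.69,0,0
rno-miR-505-5p,-1,Alkbh4,1.74,0,0
rno-miR-505-5p,-1,Kat7,1.68,0,0
rno-miR-505-5p,-1,Rnf168,1.45,0,0
rno-miR-653-3p,-1,Ezh2,1.91,1,0
rno-miR-653-3p,-1,Dnmt1,1.58,0,0
rno-miR-664-1-5p,-1,Usp49,1.81,1,0
rno-miR-664-1-5p,-1,Clock,1.56,0,0
rno-miR-664-2-5p,-1,Usp49,1.81,1,0
rno-miR-664-2-5p,-1,Clock,1.64,0,0
rno-miR-667-5p,-1,Dnmt3a,1.85,1,0
rno-miR-667-5p,-1,Prdm2,1.78,1,0
rno-miR-667-5p,-1,Carm1,1.76,0,0
rno-miR-667-5p,-1,Mier2,1.49,0,0
rno-miR-7a-5p,-1,Ezh1,1.82,1,0
rno-miR-7a-5p,-1,Prkcb,1.76,1,0
rno-miR-7a-5p,-1,Sirt5,1.65,0,0
rno-miR-7a-5p,-1,Jade1,1.59,0,0
rno-miR-7a-5p,-1,Smyd5,1.55,0,0
rno-miR-872-5p,-1,Dtx3l,1.69,0,0
rno-miR-872-5p,-1,Kat6a,1.62,0,0
rno-miR-874-3p,-1,Kdm4a,1.81,1,0
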