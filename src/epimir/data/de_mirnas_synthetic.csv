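mirna_id,fold_change,direction,p_value
rno-let-7b-3p,2.7,up,0.0275
rno-let-7c-5p,6.94,up,0.01465
rno-let-7f-1-3p,4.75,up,0.03677
rno-miR-10b-5p,4.64,up,0.047
rno-miR-126a-5p,3.85,up,0.03829
rno-miR-132-3p,4.64,up,0.04663
rno-miR-133a-3p,2.56,up,0.04802
rno-miR-133b-3p,6.97,up,0.00234
rno-miR-146b-3p,3.97,up,0.04519
rno-miR-148b-5p,3.97,up,0.04405
rno-miR-18a-3p,2.44,up,0.00225
rno-miR-217-3p,2.06,up,0.01912
rno-miR-26a-5p,2.39,up,0.03603
rno-miR-299b-5p,2.65,up,0.02179
rno-miR-322-5p,4.61,up,0.02828
rno-miR-324-3p,6.9,up,0.01546
rno-miR-330-5p,3.5,up,0.04718
rno-miR-343,7.21,up,0.04359
rno-miR-3547,6.71,up,0.0391
rno-miR-3572,9.47,up,0.00324
rno-miR-3583-3p,9.15,up,0.04013
rno-miR-3590-5p,8.24,up,0.02656
rno-miR-3593-3p,8.17,up,0.00133
rno-miR-375-5p,6.26,up,0.00889
rno-miR-376c-5p,3.12,up,0.02634
rno-miR-410-5p,3.49,up,0.0061
rno-miR-434-5p,4.36,up,0.00811
rno-miR-484,3.13,up,0.01382
rno-miR-674-3p,5.99,up,0.01213
rno-miR-741-3p,7.31,up,0.01139
rno-miR-764-5p,2.59,up,0.02943
rno-miR-874-5p,4.02,up,0.009
rno-miR-881-3p,5.5,up,0.03216
rno-miR-92b-3p,6.26,up,0.0132
let-7d-5p,7.25,down,0.02018
rno-miR-100-5p,8.63,down,0.02829
rno-miR-1193-3p,5.98,down,0.00912
rno-miR-140-3p,8.17,down,0.04477
rno-miR-142-3p,3.86,down,0.00091
rno-miR-148b-3p,6.83,down,0.04497
rno-miR-183-3p,6.06,down,0.01699
rno-miR-183-5p,4.25,down,0.00502
rno-miR-1843a-5p,7.83,down,0.01012
rno-miR-186-5p,2.88,down,0.03104
rno-miR-193a-3p,7.39,down,0.00625
rno-miR-194-5p,8.9,down,0.01029
rno-miR-195-5p,8.96,down,0.02859
rno-miR-199a-3p,3.14,down,0.0223
rno-miR-19b-3p,2.57,down,0.02533
rno-miR-204-3p,3.89,down,0.01418
rno-miR-21-3p,7.16,down,0.03879
rno-miR-22-3p,6.3,down,0.0207
rno-miR-297,8.63,down,0.02809
rno-miR-29c-3p,8.72,down,0.00128
rno-miR-300-5p,7.61,down,0.02667
rno-miR-30e-3p,4.03,down,0.04083
rno-miR-31a-5p,3.9,down,0.02988
rno-miR-342-3p,2.13,down,0.0354
rno-miR-34c-5p,5.34,down,0.00646
rno-miR-3559-5p,5.74,down,0.04514
rno-miR-421-3p,3.23,down,0.04112
rno-miR-466b-5p,9.49,down,0.03229
rno-miR-496-5p,3.36,down,0.01476
rno-miR-505-5p,4.31,down,0.03422
rno-miR-653-3p,7.33,down,0.00425
rno-miR-664-1-5p,8.17,down,0.04391
rno-miR-664-2-5p,5.95,down,0.00258
rno-miR-667-5p,5.29,down,0.01438
rno-miR-7a-5p,3.02,down,0.01307
rno-miR-872-5p,6.11,down,0.03867
rno-miR-874-3p,4.53,down,0.02209
rno-miR-synUp01,8.72,up,0.02949
rno-miR-synUp02,8.14,up,0.03488
rno-miR-synUp03,2.91,up,0.03669
rno-miR-synUp04,3.46,up,0.01579
rno-miR-synUp05,2.46,up,0.02234
rno-miR-synUp06,5.49,up,0.01748
rno-miR-synUp07,9.4,up,0.03293
rno-miR-synUp08,8.18,up,0.01181
rno-miR-synUp09,7.58,up,0.044
rno-miR-synUp10,2.03,up,0.02711
rno-miR-synUp11,7.19,up,0.02261
rno-miR-synUp12,3.88,up,0.0318
rno-miR-synUp13,3.42,up,0.03021
rno-miR-synUp14,4.24,up,0.03994
rno-miR-synUp15,2.85,up,0.0152
rno-miR-synUp16,3.11,up,0.00888
rno-miR-synDn01,4.72,down,0.03538
rno-miR-synDn02,7.55,down,0.02967
rno-miR-synDn03,6.52,down,0.01176
rno-miR-synDn04,8.52,down,0.00986
rno-miR-synDn05,3.89,down,0.02631
rno-miR-synDn06,6.56,down,0.01675
rno-miR-synDn07,4.67,down,0.0392
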