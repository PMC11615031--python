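patient_id,age,sex,technique,diagnosis,location,diameter
P1,40,male,polypectomy,tubular adenoma LGD,colon ascendens,9
P1,40,male,EMR,tubular adenoma LGD,sigmoid colon,12
P2,55,female,EMR,hyperplastic,colon transversum,2
P2,55,female,EMR,SSL without dysplasia,colon ascendens,5
P3,60,male,EMR,tubular adenoma LGD,colon descendens,8
P3,60,male,polypectomy,inflammatory,sigmoid colon,3
P4,65,male,EMR,SSL without dysplasia,colon transversum,10
P4,65,male,EMR,traditional serrated adenoma LGD,flexura hepatica,
P5,67,female,EMR,tubular adenoma LGD,flexura lienalis,15
P6,70,male,eFTR,tubular adenoma HGD,rectum,28
P7,72,female,EMR,tubulovillous adenoma LGD,colon descendens,20
P8,75,male,polypectomy,SSL with dysplasia,sigmoid colon,
P9,78,male,EMR,tubular adenoma LGD,unknown,7
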