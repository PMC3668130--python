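subject_id,group,age_at_surgery_y,survival_y,size_mm,grade,nodes,in_situ,npi_printed
SV01,survivor,54.15,15.39,15,2,1,False,4.30
SV02,survivor,40.84,19.12,50,1,0,False,3.00
SV03,survivor,36.48,19.39,80,3,0,False,5.60
SV04,survivor,41.68,19.93,20,3,0,False,4.40
SV05,survivor,32.70,20.32,,3,0,True,
SV06,survivor,40.08,20.50,8,2,0,False,3.16
SV07,survivor,37.50,20.67,28,3,0,False,4.56
SV08,survivor,34.23,21.04,35,2,0,False,3.70
SV09,survivor,42.97,21.96,,,0,True,
SV10,survivor,42.26,23.35,,,0,True,
SV11,survivor,41.15,23.50,10,3,0,False,4.20
SV12,survivor,36.76,24.08,35,2,0,False,3.70
SV13,survivor,34.80,24.38,20,3,0,False,4.40
SV14,survivor,32.47,24.83,8,3,0,False,4.16
SV15,survivor,34.84,25.04,30,3,0,False,4.60
SV16,survivor,35.98,25.41,40,3,0,False,4.80
SV17,survivor,38.03,26.19,57,2,0,False,4.15
SV18,survivor,34.08,28.14,10,3,0,False,4.20
NS01,non-survivor,41.87,0.76,120,3,2,False,7.40
NS02,non-survivor,46.46,1.16,21,3,4,False,6.42
NS03,non-survivor,39.61,1.90,40,3,2,False,5.80
NS04,non-survivor,37.83,2.28,15,3,0,False,4.30
NS05,non-survivor,56.57,2.50,20,3,5,False,6.40
NS06,non-survivor,26.90,2.69,20,3,1,False,5.40
NS07,non-survivor,43.78,4.21,18,2,0,False,3.36
NS08,non-survivor,28.07,5.43,19,2,0,False,3.38
NS09,non-survivor,38.45,5.60,30,3,1,False,5.60
NS10,non-survivor,37.45,6.79,25,3,0,False,4.50
NS11,non-survivor,43.69,8.01,30,1,1,False,3.60
NS12,non-survivor,39.22,8.07,30,3,1,False,5.60
NS13,non-survivor,40.73,8.46,15,2,0,False,3.30
NS14,non-survivor,44.02,9.32,15,2,0,False,3.30
NS15,non-survivor,42.43,13.11,45,3,1,False,5.90
NS16,non-survivor,38.46,15.73,8,2,0,False,3.16
NS17,non-survivor,31.75,21.16,10,3,0,False,4.20
NS18,non-survivor,34.59,22.82,15,3,0,False,4.30
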