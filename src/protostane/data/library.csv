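peak,rt_min,precursor_mz,error_ppm,formula,lambda_max,type_id,standard_confirmed,quantified,mz_anomalous,name,fragments
1,11.81,505.3534,1.0,C30H48O6,245,II,True,False,False,16-oxo-alisol A,487.3421:H2O;469.3317:H2O+H2O;451.3416:H2O+H2O+H2O;415.2845:C4H10O2;397.2745:C4H10O2+H2O
2,13.19,547.3638,0.5,C32H50O7,245,II,True,True,False,16-oxo-alisol A 23-acetate,529.3528:H2O;511.3421:H2O+H2O;487.3422:HAc;469.3316:HAc+H2O;415.2848:C6H12O3;397.2745:C6H12O3+H2O
3,15.63,547.3624,-2.0,C32H50O7,245,II,True,True,False,16-oxo-alisol A 24-acetate,529.3529:H2O;511.3429:H2O+H2O;487.3423:HAc;469.3318:HAc+H2O;415.2847:C6H12O3;397.2744:C6H12O3+H2O
4,16.70,507.3687,0.2,C30H50O6,,VI,True,False,False,"13,17-epoxy-alisol A",489.3577:H2O;471.3471:H2O+H2O;453.3365:H2O+H2O+H2O;417.3007:C4H10O2;399.2896:C4H10O2+H2O
5,17.31,487.3423,-0.2,C30H46O5,245,II,True,True,False,alisol C,469.3314:H2O;451.3213:H2O+H2O;415.2650:C4H8O;397.2741:H2O+C4H8O;379.3427:H2O+H2O+C4H8O
6,19.36,487.3429,1.0,C30H46O5,287,I,True,False,False,16-oxo-11-anhydro-alisol A,469.3319:H2O;451.3215:H2O+H2O;397.2742:C4H10O2
7,19.72,489.3562,-2.7,C30H48O5,245,VII,False,False,False,16-oxo-11-deoxy-alisol A,471.3471:H2O;453.3367:H2O+H2O;399.2896:C4H10O2
8,21.46,549.3798,1.3,C32H52O7,,VI,True,False,False,"13,17-epoxy-alisol A 24-acetate",531.3685:H2O;513.3579:H2O+H2O;489.3585:HAc;471.3470:HAc+H2O;417.3005:C6H12O3;399.2896:C6H12O3+H2O
9,23.30,471.3464,-2.1,C30H46O4,,IV,False,False,False,"16,23-oxido-alisol B",453.3367:H2O;381.2791:C4H8O+H2O;339.2684:C4H8O+H2O+C2H2O
10,23.37,489.3583,0.6,C30H48O5,,IV,True,True,False,alisol F,471.3472:H2O;453.3366:H2O+H2O;381.2798:H2O+C4H10O2;339.2687:H2O+C4H10O2+C2H2O
11,24.33,529.3522,-1.3,C32H48O6,245,II,True,True,False,alisol C 23-acetate,511.3424:H2O;469.3313:HAc;451.3212:HAc+H2O;415.2652:C6H10O2;397.2741:C6H10O2+H2O
12,24.75,489.3586,1.2,C30H48O5,,VI,True,False,False,"13,17-epoxy-alisol B",471.3477:H2O;453.3363:H2O+H2O;417.3006:C4H8O;399.2895:C4H8O+H2O
13,25.46,471.3482,1.7,C30H46O4,245,VII,False,False,False,11-deoxy-alisol C,453.3368:H2O;399.2894:C4H8O
14,25.91,469.3315,-0.6,C30H44O4,287,I,True,True,False,alisol L,451.3216:H2O;397.2745:C4H8O
15,27.00,531.3694,1.5,C32H50O6,,IV,True,True,False,alisol F 24-acetate,513.3585:H2O;495.3598:H2O+H2O;453.3367:H2O+HAc;435.3592:H2O+H2O+HAc;381.2791:H2O+C6H12O3;339.2684:H2O+C6H12O3+C2H2O
16,27.75,491.3731,0.0,C30H50O5,,III,True,True,False,alisol A,473.3630:H2O;455.3524:H2O+H2O;437.3418:H2O+H2O+H2O;383.2984:H2O+C4H10O2
17,29.07,533.3773,0.4,C32H52O6,,III,True,True,True,alisol A 23-acetate,515.3735:H2O;497.3633:H2O+H2O;455.3526:HAc+H2O;437.3422:HAc+H2O+H2O;383.2983:C6H12O3+H2O
18,33.90,533.3848,1.1,C32H52O6,,III,True,True,False,alisol A 24-acetate,515.3736:H2O;497.3634:H2O+H2O;455.3528:HAc+H2O;437.3420:HAc+H2O+H2O;383.2981:C6H12O3+H2O
19,34.95,531.3685,-0.2,C32H50O6,,VI,True,False,False,"13,17-epoxy-alisol B 23-acetate",513.3581:H2O;495.3476:H2O+H2O;471.3478:HAc;453.3367:HAc+H2O;417.3008:C6H10O2;399.2895:C6H10O2+H2O
20,35.87,511.3418,-1.2,C32H46O5,287,I,True,False,False,alisol L 23-acetate,451.3321:HAc;397.2743:C6H10O2
21,38.87,473.3638,1.5,C30H48O4,,III,True,True,False,alisol G,455.3527:H2O;437.3425:H2O+H2O;383.2981:H2O+C4H8O
22,40.71,473.3639,1.7,C30H48O4,,III,True,True,False,alisol B,455.3523:H2O;437.2426:H2O+H2O;383.2982:H2O+C4H8O
23,49.06,515.3739,0.4,C32H50O5,,III,True,True,False,alisol B 23-acetate,497.3631:H2O;479.3519:H2O+H2O;437.3431:H2O+HAc;383.2983:H2O+C6H10O2
24,54.55,457.3675,-1.5,C30H48O3,,V,True,True,False,11-deoxy-alisol B,439.3574:H2O;385.3102:C4H8O
25,61.12,499.3794,1.4,C32H50O4,,V,False,False,False,11-deoxy-alisol B 23-acetate,439.3578:HAc;385.3105:C6H10O2
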