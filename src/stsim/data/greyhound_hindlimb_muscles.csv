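joint,muscle,abbreviation,pcsa_cm2,pennation_deg,fmax_N,fmax_lit_N,lit_group,fibre_opt_measured_cm,tsl_measured_cm,fibre_opt_model_cm,tsl_model_cm
Hip,Adductor brevis,AddBrev,3.49,7,103,770,Add,2.94,0.71,2.94,0.71
Hip,Adductor magnus,AddMag,14.11,0,423,,Add,12.50,1.67,12.50,1.67
Hip,Gluteus medius,GMed,24.86,10,723,650,,4.00,3.60,4.00,3.60
Hip,Gluteus profundus,GInt,4.35,8,128,230,,2.08,0.67,2.08,0.71
Hip,Gluteus superficialis,GSup,4.37,22,113,840,,5.07,0.01,5.07,1.40
Hip,Iliopsoas,IP,8.76,12,252,,,6.45,5.00,6.45,5.00
Hip,Obturator externus,ObtExt,1.89,0,57,,,5.93,0.29,5.01,0.01
Hip,Obturator internus,ObtInt,3.54,0,106,,,2.27,1.27,2.27,2.20
Hip,Pectineus,Pect,4.54,14,128,,,1.78,14.21,1.78,13.61
Hip,Quadratus femoris,QF,1.44,0,43,,,5.06,0.07,5.06,0.07
Hip,Tensor fascia lata,TFL1,18.02,32,389,310,,2.71,22.60,2.71,23.55
Hip/Knee,Biceps femoris anterior,BF2,11.44,0,343,960,BF,12.00,14.95,12.20,18.95
Hip/Knee,Biceps femoris posterior,BF1,9.32,0,279,,BF,12.00,16.49,12.00,17.40
Hip/Knee,Gracilis,Gra,15.65,0,470,870,,6.06,19.40,6.06,19.40
Hip/Knee,Rectus femoris,RF,12.20,12,350,790,,3.98,23.39,5.50,21.35
Hip/Knee,Sartorius caudalis,Sart,2.39,0,72,310,Sart,20.00,4.40,20.00,5.80
Hip/Knee,Sartorius cranialis,Sart2,0.57,0,17,,Sart,24.65,0.05,24.65,0.60
Hip/Knee,Semimembranosus,SM,7.62,0,229,240,,21.26,1.06,21.26,1.06
Hip/Knee,Semitendinosus,ST,5.41,0,162,360,,18.34,6.46,18.34,6.46
Knee,Vastus lateralis & intermedius,VL,12.22,13,348,550,,7.86,17.57,7.86,17.57
Knee,Vastus medialis,VM,6.66,14,188,770,,8.63,17.12,8.63,17.12
Knee/Ankle,Flexor digitorum superficialis,FDS,37.16,28,864,1260,,1.16,25.27,4.66,21.36
Knee/Ankle,Gastrocnemius lateralis,GasL,18.07,26,439,680,,1.29,26.20,3.09,24.40
Knee/Ankle,Gastrocnemius medialis,GasM,20.30,27,486,610,,1.85,26.50,2.20,26.15
Ankle,Extensor digitorum lateralis,ExtDigLat,0.83,10,24,,,1.28,34.68,1.28,34.41
Ankle,Extensor digitorum longus,ExtDigLong,2.94,0,88,155,,5.14,30.60,5.14,30.60
Ankle,Flexor digitorum profundus,FDP,24.99,31,551,630,,1.54,37.24,1.54,36.59
Ankle,Peroneus longus,PerLong,2.00,0,60,280,,2.45,25.54,2.45,24.92
Ankle,Tibialis cranialis,TibCran,1.90,5,57,120,,10.80,12.68,10.80,12.68
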