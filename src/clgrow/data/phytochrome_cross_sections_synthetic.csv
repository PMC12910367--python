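# Synthetic phytochrome photoconversion cross-section table (relative units).
# Gaussian-mixture model of Pr/Pfr photon cross-sections, calibrated to
# published photoequilibrium anchors: PSS(660 nm) ~ 0.89, PSS(730 nm) low,
# and a deep-red/white + far-red lamp recipe (R:FR 3.5) -> PSS ~ 0.82.
# This is a constructed stand-in table, not measured phytochrome data.
wavelength_nm,sigma_r,sigma_fr
300,3.301634e-02,4.792761e-03
302,3.756160e-02,5.424126e-03
304,4.259328e-02,6.123334e-03
306,4.814155e-02,6.895415e-03
308,5.423515e-02,7.745459e-03
310,6.090088e-02,8.678570e-03
312,6.816291e-02,9.699814e-03
314,7.604220e-02,1.081416e-02
316,8.455573e-02,1.202643e-02
318,9.371591e-02,1.334120e-02
320,1.035298e-01,1.476274e-02
322,1.139986e-01,1.629497e-02
324,1.251168e-01,1.794133e-02
326,1.368716e-01,1.970469e-02
328,1.492427e-01,2.158733e-02
330,1.622015e-01,2.359080e-02
332,1.757108e-01,2.571583e-02
334,1.897247e-01,2.796229e-02
336,2.041885e-01,3.032907e-02
338,2.190385e-01,3.281405e-02
340,2.342026e-01,3.541398e-02
342,2.496000e-01,3.812449e-02
344,2.651427e-01,4.093997e-02
346,2.807349e-01,4.385360e-02
348,2.962751e-01,4.685730e-02
350,3.116562e-01,4.994172e-02
352,3.267671e-01,5.309627e-02
354,3.414937e-01,5.630913e-02
356,3.557206e-01,5.956730e-02
358,3.693322e-01,6.285665e-02
360,3.822146e-01,6.616203e-02
362,3.942569e-01,6.946734e-02
364,4.053528e-01,7.275566e-02
366,4.154024e-01,7.600938e-02
368,4.243133e-01,7.921033e-02
370,4.320024e-01,8.233998e-02
372,4.383971e-01,8.537956e-02
374,4.434361e-01,8.831030e-02
376,4.470708e-01,9.111357e-02
378,4.492659e-01,9.377110e-02
380,4.500000e-01,9.626519e-02
382,4.492659e-01,9.857885e-02
384,4.470708e-01,1.006961e-01
386,4.434361e-01,1.026019e-01
388,4.383971e-01,1.042828e-01
390,4.320024e-01,1.057266e-01
392,4.243133e-01,1.069228e-01
394,4.154024e-01,1.078624e-01
396,4.053528e-01,1.085387e-01
398,3.942569e-01,1.089465e-01
400,3.822146e-01,1.090827e-01
402,3.693322e-01,1.089465e-01
404,3.557206e-01,1.085387e-01
406,3.414937e-01,1.078624e-01
408,3.267671e-01,1.069228e-01
410,3.116562e-01,1.057266e-01
412,2.962751e-01,1.042828e-01
414,2.807349e-01,1.026019e-01
416,2.651427e-01,1.006961e-01
418,2.496000e-01,9.857885e-02
420,2.342026e-01,9.626519e-02
422,2.190385e-01,9.377110e-02
424,2.041885e-01,9.111357e-02
426,1.897247e-01,8.831030e-02
428,1.757108e-01,8.537956e-02
430,1.622015e-01,8.233998e-02
432,1.492427e-01,7.921033e-02
434,1.368716e-01,7.600938e-02
436,1.251168e-01,7.275566e-02
438,1.139986e-01,6.946734e-02
440,1.035298e-01,6.616203e-02
442,9.371591e-02,6.285665e-02
444,8.455573e-02,5.956730e-02
446,7.604220e-02,5.630913e-02
448,6.816291e-02,5.309627e-02
450,6.090088e-02,4.994172e-02
452,5.423515e-02,4.685730e-02
454,4.814155e-02,4.385360e-02
456,4.259328e-02,4.093997e-02
458,3.756160e-02,3.812449e-02
460,3.301634e-02,3.541398e-02
462,2.892649e-02,3.281405e-02
464,2.526064e-02,3.032907e-02
466,2.198746e-02,2.796229e-02
468,1.907600e-02,2.571583e-02
470,1.649612e-02,2.359080e-02
472,1.421864e-02,2.158733e-02
474,1.221564e-02,1.970469e-02
476,1.046059e-02,1.794133e-02
478,8.928493e-03,1.629497e-02
480,7.595948e-03,1.476274e-02
482,6.441214e-03,1.334120e-02
484,5.444216e-03,1.202643e-02
486,4.586536e-03,1.081416e-02
488,3.851379e-03,9.699815e-03
490,3.223514e-03,8.678571e-03
492,2.689210e-03,7.745460e-03
494,2.236155e-03,6.895417e-03
496,1.853365e-03,6.123337e-03
498,1.531094e-03,5.424130e-03
500,1.260737e-03,4.792767e-03
502,1.034735e-03,4.224321e-03
504,8.464787e-04,3.714002e-03
506,6.902156e-04,3.257180e-03
508,5.609649e-04,2.849419e-03
510,4.544321e-04,2.486487e-03
512,3.669319e-04,2.164371e-03
514,2.953154e-04,1.879291e-03
516,2.369046e-04,1.627701e-03
518,1.894316e-04,1.406293e-03
520,1.509847e-04,1.211998e-03
522,1.199595e-04,1.041980e-03
524,9.501614e-05,8.936324e-04
526,7.504114e-05,7.645694e-04
528,5.911481e-05,6.526202e-04
530,4.648299e-05,5.558181e-04
532,3.653339e-05,4.723914e-04
534,2.877626e-05,4.007534e-04
536,2.282946e-05,3.394924e-04
538,1.840784e-05,2.873630e-04
540,1.531741e-05,2.432769e-04
542,1.345466e-05,2.062955e-04
544,1.281196e-05,1.756235e-04
546,1.349012e-05,1.506043e-04
548,1.571966e-05,1.307165e-04
550,1.989299e-05,1.155734e-04
552,2.661018e-05,1.049238e-04
554,3.674165e-05,9.865612e-05
556,5.151216e-05,9.680469e-05
558,7.261101e-05,9.955953e-05
560,1.023347e-04,1.072789e-04
562,1.437690e-04,1.205056e-04
564,2.010183e-04,1.399863e-04
566,2.794915e-04,1.666952e-04
568,3.862532e-04,2.018606e-04
570,5.304509e-04,2.469956e-04
572,7.238267e-04,3.039323e-04
574,9.813241e-04,3.748584e-04
576,1.321794e-03,4.623576e-04
578,1.768809e-03,5.694517e-04
580,2.351580e-03,6.996438e-04
582,3.105972e-03,8.569633e-04
584,4.075619e-03,1.046009e-03
586,5.313089e-03,1.271990e-03
588,6.881096e-03,1.540766e-03
590,8.853705e-03,1.858879e-03
592,1.131747e-02,2.233583e-03
594,1.437243e-02,2.672857e-03
596,1.813293e-02,3.185418e-03
598,2.272807e-02,3.780713e-03
600,2.830177e-02,4.468901e-03
602,3.501236e-02,5.260821e-03
604,4.303144e-02,6.167935e-03
606,5.254206e-02,7.202265e-03
608,6.373603e-02,8.376299e-03
610,7.681031e-02,9.702890e-03
612,9.196250e-02,1.119513e-02
614,1.093852e-01,1.286620e-02
616,1.292597e-01,1.472924e-02
618,1.517485e-01,1.679716e-02
620,1.769875e-01,1.908247e-02
622,2.050771e-01,2.159709e-02
624,2.360742e-01,2.435219e-02
626,2.699830e-01,2.735802e-02
628,3.067476e-01,3.062372e-02
630,3.462442e-01,3.415717e-02
632,3.882761e-01,3.796487e-02
634,4.325690e-01,4.205184e-02
636,4.787698e-01,4.642152e-02
638,5.264473e-01,5.107572e-02
640,5.750951e-01,5.601459e-02
642,6.241387e-01,6.123666e-02
644,6.729446e-01,6.673884e-02
646,7.208321e-01,7.251650e-02
648,7.670888e-01,7.856357e-02
650,8.109869e-01,8.487262e-02
652,8.518021e-01,9.143499e-02
654,8.888332e-01,9.824088e-02
656,9.214219e-01,1.052795e-01
658,9.489721e-01,1.125392e-01
660,9.709683e-01,1.200073e-01
662,9.869914e-01,1.276707e-01
664,9.967319e-01,1.355151e-01
666,1.000000e+00,1.435257e-01
668,9.967319e-01,1.516867e-01
670,9.869914e-01,1.599815e-01
672,9.709683e-01,1.683921e-01
674,9.489721e-01,1.768994e-01
676,9.214219e-01,1.854827e-01
678,8.888332e-01,1.941194e-01
680,8.518021e-01,2.027853e-01
682,8.109869e-01,2.114534e-01
684,7.670888e-01,2.200947e-01
686,7.208321e-01,2.286773e-01
688,6.729446e-01,2.371667e-01
690,6.241387e-01,2.455255e-01
692,5.750951e-01,2.537133e-01
694,5.264473e-01,2.616872e-01
696,4.787698e-01,2.694016e-01
698,4.325690e-01,2.768088e-01
700,3.882761e-01,2.838592e-01
702,3.462442e-01,2.905018e-01
704,3.067476e-01,2.966849e-01
706,2.699830e-01,3.023567e-01
708,2.360742e-01,3.074662e-01
710,2.050771e-01,3.119638e-01
712,1.769875e-01,3.158022e-01
714,1.517485e-01,3.189375e-01
716,1.292597e-01,3.213296e-01
718,1.093852e-01,3.229435e-01
720,9.196250e-02,3.237498e-01
722,7.681031e-02,3.237253e-01
724,6.373602e-02,3.228540e-01
726,5.254206e-02,3.211272e-01
728,4.303144e-02,3.185439e-01
730,3.501236e-02,3.151112e-01
732,2.830177e-02,3.108445e-01
734,2.272806e-02,3.057668e-01
736,1.813293e-02,2.999091e-01
738,1.437243e-02,2.933098e-01
740,1.131746e-02,2.860144e-01
742,8.853699e-03,2.780742e-01
744,6.881086e-03,2.695465e-01
746,5.313075e-03,2.604932e-01
748,4.075600e-03,2.509799e-01
750,3.105946e-03,2.410751e-01
752,2.351543e-03,2.308494e-01
754,1.768759e-03,2.203742e-01
756,1.321725e-03,2.097209e-01
758,9.812282e-04,1.989599e-01
760,7.236953e-04,1.881597e-01
762,5.302714e-04,1.773864e-01
764,3.860089e-04,1.667024e-01
766,2.791599e-04,1.561664e-01
768,2.005698e-04,1.458324e-01
770,1.431643e-04,1.357493e-01
772,1.015221e-04,1.259609e-01
774,7.152256e-05,1.165053e-01
776,5.005901e-05,1.074151e-01
778,3.480792e-05,9.871712e-02
780,2.404532e-05,9.043273e-02
782,1.650213e-05,8.257777e-02
784,1.125138e-05,7.516290e-02
786,7.621289e-06,6.819390e-02
788,5.128705e-06,6.167202e-02
790,3.428812e-06,5.559433e-02
792,2.277384e-06,4.995415e-02
794,1.502746e-06,4.474151e-02
796,9.851258e-07,3.994360e-02
798,6.415853e-07,3.554517e-02
800,4.151201e-07,3.152901e-02
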