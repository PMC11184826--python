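t,omega,jerk
0.0,-9.316632903559976e-05,2.0
0.01,-0.00023923198193876786,2.0
0.02,-0.0005919953648329888,2.0
0.03,-0.0014117447712136066,2.0
0.04,-0.00324438872072672,2.0
0.05,-0.007185357672434111,2.0
0.06,-0.015335668532967894,2.0
0.07,-0.03154248085553462,2.0
0.08,-0.06252127073187037,2.0
0.09,-0.11942590957434142,2.0
0.1,-0.21984071697025662,2.0
0.11,-0.38999273652490085,2.0
0.12,-0.666720360824736,2.0
0.13,-1.0984232892116623,2.0
0.14,-1.743952166173426,2.0
0.15,-2.6683220997866637,2.0
0.16,-3.9344213578220004,2.0
0.17,-5.590654691195359,2.0
0.18,-7.655690849968542,2.0
0.19,-10.102947291990917,2.0
0.2,-12.848705001008556,2.0
0.21,-15.748270578534466,2.0
0.22,-18.603980505604845,2.0000000000000018
0.23,-21.187025829171017,2.0000000000001443
0.24,-23.272504845005486,2.000000000008496
0.25,-24.68457433163919,2.0000000003848477
0.26,-25.34674028353749,2.0000000134017886
0.27,-25.331150891224464,2.0000003587763295
0.28,-24.89912817160319,2.0000073836639
0.29,-24.52155814194451,2.0001168173030193
0.3,-24.861973365756285,2.0014207888808397
0.31,-26.700644353023918,2.0132843112459855
0.32,-30.782380101370066,2.0954851101958902
0.33,-37.59226958191668,2.5276177327810916
0.34,-47.103211442917925,4.241249633928211
0.35,-58.582726957424065,9.31894019411218
0.36,-70.56601410024156,20.37355880348259
0.37,-81.06979941236574,37.458918658009765
0.38,-88.03320041852668,54.607154259738536
0.39,-89.86132889595389,62.0
0.4,-85.87506395916712,54.60715425973844
0.41,-76.48676289657323,37.458918658009765
0.42,-63.02956861283825,20.373558803482485
0.43,-47.314308922437334,9.31894019411218
0.44,-31.094965682920037,4.2412496339281915
0.45,-15.638549305443876,2.5276177327810916
0.46,-1.521443153249541,2.095485110195889
0.47,11.336992835300064,2.0132843112459855
0.48,23.480718107596896,2.0014207888808397
0.49,35.67106150626202,2.0001168173030193
0.5,48.6743096647447,2.0000073836639
0.51,63.12234606085084,2.0000003587763295
0.52,79.44468082985298,2.0000000134017886
0.53,97.84905098795677,2.0000000003848477
0.54,118.32591956685914,2.000000000008496
0.55,140.66083488862236,2.0000000000001443
0.56,164.44884720607328,2.0000000000000018
0.57,189.112101180172,2.0
0.58,213.9243500382823,2.0
0.59,238.04560461315302,2.0
0.6,260.5680055246987,2.0
0.61,280.57147830612865,2.0
0.62,297.185490282103,2.0
0.63,309.6516277949612,2.0
0.64,317.38092797606396,2.0
0.65,319.9999999597794,2.0
0.66,317.3809279761238,2.0
0.67,309.65162779521404,2.0
0.68,297.1854902830806,2.0
0.69,280.5714783097633,2.0
0.7,260.5680055377176,2.0
0.71,238.04560465809226,2.0
0.72,213.92435018777226,2.0
0.73,189.1121016593975,2.0
0.74,164.4488486865654,2.0000000000000018
0.75,140.6608392963131,2.0000000000001443
0.76,118.32593221290962,2.000000000008496
0.77,97.84908595327971,2.0000000003848477
0.78,79.44477399618229,2.0000000134017886
0.79,63.12258529283365,2.0000003587763295
0.8,48.674901660111594,2.0000073836639
0.81,35.67247325103932,2.0001168173030193
0.82,23.483962496334357,2.0014207888808397
0.83,11.344178193017859,2.0132843112459855
0.84,-1.5061074845962708,2.0954851101958916
0.85,-15.60700682427348,2.5276177327810974
0.86,-31.032444411379057,4.241249633928211
0.87,-47.194883010823204,9.31894019411218
0.88,-62.809727890846325,20.373558803482698
0.89,-76.09677014810865,37.45891865800991
0.9,-85.20834357170497,54.607154259738536
0.91,-88.7629055553687,62.0
0.92,-86.28924819319955,54.60715425973834
0.93,-78.40147746856292,37.45891865800964
0.94,-66.63159440319728,20.373558803482485
0.95,-52.99208142825079,9.31894019411218
0.96,-39.44756194146668,4.2412496339281684
0.97,-27.489488545245138,2.527617732781085
0.98,-17.934287668786567,2.095485110195889
0.99,-10.954465578269893,2.0132843112459855
1.0,-6.264646812315074,2.0014207888808397
1.01,-3.3542969101944737,2.0001168173030193
1.02,-1.6815115461218901,2.0000073836639
1.03,-0.7891811992630029,2.0000003587763295
1.04,-0.3467402835374838,2.0000000134017886
1.05,-0.1426046396777299,2.0000000003848477
1.06,-0.05488821952419257,2.000000000008496
1.07,-0.019764597421003272,2.0000000000001443
1.08,-0.006653952163685027,2.0000000000000018
1.09,-0.0020918037804597985,2.0
1.1,-0.0006125684251202159,2.0
1.11,-0.0001662553194709726,2.0
1.12,-4.1348517482448586e-05,2.0
1.13,-9.162022092978185e-06,2.0
1.14,-1.6607778189613168e-06,2.0
1.15,-1.559839177226743e-07,2.0
1.16,5.9153611051001634e-08,2.0
1.17,5.137352303267286e-08,2.0
1.18,2.6637443221962963e-08,2.0
1.19,1.1939754414937015e-08,2.0
1.2,5.0218648947132846e-09,2.0
1.21,2.039777279972354e-09,2.0
1.22,8.09195686132233e-10,2.0
1.23,3.1493627052354296e-10,2.0
1.24,1.204586345225947e-10,2.0
1.25,4.530788245615655e-11,2.0
1.26,1.6761998046364693e-11,2.0
1.27,6.099940143170417e-12,2.0
1.28,2.183649894967137e-12,2.0
1.29,7.689551733485205e-13,2.0
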