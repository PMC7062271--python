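# synthetic 64-direction uniform scheme: frozen electrostatic-repulsion design (energy yardstick)
-0.93402987 0.27570367 0.22131566 -0.98332244 -0.52657036 -0.76602456 -0.55481197 0.89815895 0.76334478 0.98550189 -0.77855364 -0.01429773 -0.05589571 -0.97180410 -0.87316931 0.69648069 0.44152358 0.50482362 -0.33310758 0.88022348 -0.34166983 0.92316283 -0.62913071 -0.84901202 0.22161489 -0.60157231 -0.89877190 0.18401310 0.67425890 0.75638277 0.86897025 -0.10795773 0.49034389 -0.09174793 -0.71374168 -0.83662126 -0.41667565 0.42426099 -0.36698075 -0.64962854 0.69733869 0.74352932 0.13110247 0.21368362 -0.70802502 0.52078339 0.65751224 -0.47985695 -0.17430347 -0.62854097 0.43495675 -0.07789318 -0.38110373 0.12795107 0.47305134 0.22993933 -0.45202739 0.40103136 -0.36232975 -0.19622463 -0.07281117 0.10901954 0.17917503 -0.13466819
0.35685340 -0.96043921 0.97437383 -0.17470491 -0.84826218 -0.64008549 0.82856531 0.41815060 -0.63110064 -0.07751577 0.60463746 -0.98170744 0.97892873 0.10296542 -0.42188023 0.67310243 0.86199462 -0.82575165 -0.89578940 -0.35878801 0.88679418 0.18440726 -0.69548992 0.38035050 -0.89606320 0.68814212 -0.16324982 0.89315757 -0.59700605 0.45943723 -0.09081237 -0.85718961 0.69703321 0.84061355 -0.45261266 0.11944524 -0.70654174 -0.69655181 0.70363420 0.44424649 -0.35686600 0.20198341 -0.73389108 0.70101858 -0.16896092 0.45957244 -0.07908487 -0.44375026 -0.62531528 0.15306934 -0.44839597 0.61486465 0.46085824 -0.49392103 0.17993509 0.43917202 -0.14004070 -0.15423675 0.17555209 -0.34634172 0.33167061 -0.21046866 0.12062144 -0.01699821
0.01561556 0.03929383 0.04018724 0.05054868 0.05634660 0.05913488 0.07525422 0.13586969 0.13790117 0.15092161 0.16813022 0.18985805 0.19640317 0.21212005 0.24411560 0.24869214 0.24904259 0.25156974 0.29427997 0.31060874 0.31121986 0.33728971 0.34711428 0.36675888 0.38465255 0.40567373 0.40688890 0.41037634 0.43469381 0.46562059 0.48646051 0.50355843 0.52317070 0.53380819 0.53452277 0.53460050 0.57199666 0.57863477 0.60846039 0.61695042 0.62158298 0.63746910 0.66649533 0.68037655 0.68567688 0.71942883 0.74928181 0.75685072 0.76065702 0.76256542 0.78086727 0.78477648 0.80147965 0.86004101 0.86246495 0.86847904 0.88094259 0.90298664 0.91536802 0.91735670 0.94058128 0.97150280 0.97639478 0.99074494
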