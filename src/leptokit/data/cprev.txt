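# exchangeabilities (symmetric, PAML amino-acid order) then equilibrium frequencies
A R N D C Q E G H I L K M F P S T W Y V
0 105 227 175 669 157 499 665 66 145 197 236 185 68 490 2440 1340 14 56 968
105 0 357 43 823 1745 152 243 715 136 203 4482 125 53 87 385 314 230 323 92
227 357 0 4435 538 768 1055 653 1405 168 113 2430 61 97 173 2085 1393 40 754 83
175 43 4435 0 10 400 3691 431 331 10 10 412 47 22 170 590 266 18 281 75
669 823 538 10 0 10 10 303 441 280 396 48 159 726 285 2331 576 435 1466 592
157 1745 768 400 10 0 3122 133 1269 92 286 3313 202 10 323 396 241 53 391 54
499 152 1055 3691 10 3122 0 379 162 148 82 2629 113 145 185 568 369 63 142 200
665 243 653 431 303 133 379 0 19 40 20 263 21 25 28 691 92 82 10 91
66 715 1405 331 441 1269 162 19 0 29 66 305 10 127 152 303 32 69 1971 25
145 136 168 10 280 92 148 40 29 0 1745 345 1772 454 117 216 1040 42 89 4797
197 203 113 10 396 286 82 20 66 1745 0 218 1351 1268 219 516 156 159 189 865
236 4482 2430 412 48 3313 2629 263 305 345 218 0 193 72 302 868 918 10 247 249
185 125 61 47 159 202 113 21 10 1772 1351 193 0 327 100 93 645 86 215 475
68 53 97 22 726 10 145 25 127 454 1268 72 327 0 43 487 148 468 2370 317
490 87 173 170 285 323 185 28 152 117 219 302 100 43 0 1202 260 49 97 122
2440 385 2085 590 2331 396 568 691 303 216 516 868 93 487 1202 0 2151 73 522 167
1340 314 1393 266 576 241 369 92 32 1040 156 918 645 148 260 2151 0 29 71 760
14 230 40 18 435 53 63 82 69 42 159 10 86 468 49 73 29 0 346 10
56 323 754 281 1466 391 142 10 1971 89 189 247 215 2370 97 522 71 346 0 119
968 92 83 75 592 54 200 91 25 4797 865 249 475 317 122 167 760 10 119 0
0.0755 0.0621 0.041 0.0371 0.0091 0.0382 0.0495 0.0838 0.0246 0.0806 0.1011 0.0504 0.022 0.0506 0.0431 0.0622 0.0543 0.0181 0.0307 0.066
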