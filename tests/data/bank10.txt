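# taamkit bank 1
entry H000
element H
group 1x
frame 1x_1-ZaXany
inconsistent no
neighbor 1 a O
neighbor 2 a1 X attach=a
kappa 1.152435 0.003000
pval 0.847818 0.005000
kappa_prime 1.195871 0.003000
plm 1 0 0.268778 0.009219
plm 2 0 0.104218 0.005799
end
entry H001
element H
group 1x
frame 1x_1-ZaXany
inconsistent no
neighbor 1 a O
neighbor 2 a1 X attach=a
kappa 1.149823 0.003000
pval 0.851958 0.005000
kappa_prime 1.197464 0.003000
plm 1 0 0.290098 0.004740
plm 2 0 0.083237 0.027063
plm 3 0 0.015249 0.012158
end
entry H100
element H
group 1x
frame 1x_1-ZaXany
inconsistent no
neighbor 1 a C
neighbor 2 a1 X attach=a
kappa 1.051799 0.003000
pval 1.050918 0.005000
kappa_prime 1.099157 0.003000
plm 1 0 0.117625 0.023477
plm 2 0 0.050397 0.018818
end
entry H101
element H
group 1x
frame 1x_1-ZaXany
inconsistent no
neighbor 1 a C
neighbor 2 a1 X attach=a
kappa 1.050270 0.003000
pval 1.049070 0.005000
kappa_prime 1.098325 0.003000
plm 1 0 0.111891 0.044922
plm 2 0 0.041160 0.029639
end
entry C200
element C
group 4n
frame 4n_41-ZabXc
inconsistent no
neighbor 1 a C
neighbor 1 b C
neighbor 1 c C
neighbor 1 d C
neighbor 2 a1 X attach=a
neighbor 2 b2 X attach=b
kappa 0.986649 0.003000
pval 4.046878 0.005000
kappa_prime 0.861345 0.003000
plm 3 2 -0.235396 0.042857
end
entry C201
element C
group 4n
frame 4n_41-ZabXc
inconsistent no
neighbor 1 a C
neighbor 1 b C
neighbor 1 c C
neighbor 1 d C
neighbor 2 a1 X attach=a
neighbor 2 b2 X attach=b
kappa 0.988818 0.003000
pval 4.057494 0.005000
kappa_prime 0.862230 0.003000
plm 3 -1 0.018217 0.017737
plm 3 2 -0.226798 0.009872
end
entry C300
element C
group 3p
frame 3p_21-XabYa
inconsistent no
neighbor 1 a C planar
neighbor 1 b C planar
neighbor 1 c C planar
neighbor 2 a1 X attach=a
kappa 0.984451 0.003000
pval 3.997166 0.005000
kappa_prime 0.920006 0.003000
plm 3 3 0.296014 0.011407
end
entry C301
element C
group 3p
frame 3p_21-XabYa
inconsistent no
neighbor 1 a C planar
neighbor 1 b C planar
neighbor 1 c C planar
neighbor 2 a1 X attach=a
kappa 0.987026 0.003000
pval 4.010544 0.005000
kappa_prime 0.918740 0.003000
plm 3 3 0.320987 0.036566
end
entry C400
element C
group 2x
frame 2x_1-ZaXany
inconsistent no
neighbor 1 a C
neighbor 1 b N
neighbor 2 a1 X attach=a
kappa 0.998919 0.003000
pval 3.952363 0.005000
kappa_prime 0.950611 0.003000
plm 2 0 0.189317 0.034324
plm 3 0 0.017597 0.008850
end
entry C401
element C
group 2x
frame 2x_1-ZaXany
inconsistent no
neighbor 1 a C
neighbor 1 b N
neighbor 2 a1 X attach=a
kappa 0.998951 0.003000
pval 3.961261 0.005000
kappa_prime 0.950057 0.003000
plm 2 0 0.193894 0.008958
end
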