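major_group,nll,k_corn,sigma_k_corn,k_wheat,sigma_k_wheat,k_aoc,sigma_k_aoc,k_seu,sigma_k_seu,k_ceu,sigma_k_ceu,k_neu,sigma_k_neu,alpha,sigma_alpha
H,87.7,0.542,0.086,1.900,0.310,2.746,0.391,1.065,0.183,1.150,0.178,2.364,0.508,0.906,0.016
F,118.2,0.574,0.135,3.707,0.540,2.353,0.467,0.862,0.280,1.382,0.422,1.326,0.438,0.988,0.027
I,110.2,1.702,0.586,0.721,0.322,1.980,0.836,0.810,0.420,1.168,0.536,0.868,0.364,1.092,0.051
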