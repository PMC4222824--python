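name	vcmax_default_umol	vcmax_lo_umol	vcmax_hi_umol	pathway
Tropical broadleaf trees	65	1	300	C3
Warm-temperate broadleaf trees	40	1	300	C3
Temperate broadleaf trees	30	1	300	C3
Boreal broadleaf trees	30	1	300	C3
Temperate conifer trees	30	1	300	C3
Boreal conifer trees	20	1	300	C3
Shrub	27.5	1	300	C3
C3 herbaceous	25	1	300	C3
C4 herbaceous	15	1	300	C4
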