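label	hemisphere	x	y	z	icn
lh_bankssts	L	-56.0	-45.0	8.0	default-mode
lh_caudalanteriorcingulate	L	-5.0	20.0	28.0	ventral-attention
lh_caudalmiddlefrontal	L	-36.0	12.0	46.0	dorsal-attention
lh_cuneus	L	-7.0	-80.0	26.0	visual
lh_entorhinal	L	-26.0	-8.0	-32.0	limbic
lh_fusiform	L	-36.0	-45.0	-20.0	visual
lh_inferiorparietal	L	-42.0	-62.0	36.0	default-mode
lh_inferiortemporal	L	-50.0	-32.0	-24.0	default-mode
lh_isthmuscingulate	L	-7.0	-45.0	26.0	default-mode
lh_lateraloccipital	L	-32.0	-86.0	2.0	visual
lh_lateralorbitofrontal	L	-24.0	30.0	-16.0	limbic
lh_lingual	L	-14.0	-70.0	-6.0	visual
lh_medialorbitofrontal	L	-6.0	36.0	-16.0	limbic
lh_middletemporal	L	-58.0	-30.0	-10.0	default-mode
lh_parahippocampal	L	-26.0	-32.0	-18.0	limbic
lh_paracentral	L	-8.0	-26.0	58.0	somato-motor
lh_parsopercularis	L	-48.0	14.0	14.0	ventral-attention
lh_parsorbitalis	L	-44.0	38.0	-10.0	fronto-parietal
lh_parstriangularis	L	-46.0	30.0	8.0	fronto-parietal
lh_pericalcarine	L	-10.0	-82.0	8.0	visual
lh_postcentral	L	-42.0	-24.0	48.0	somato-motor
lh_posteriorcingulate	L	-6.0	-22.0	38.0	default-mode
lh_precentral	L	-38.0	-12.0	46.0	somato-motor
lh_precuneus	L	-9.0	-58.0	40.0	default-mode
lh_rostralanteriorcingulate	L	-5.0	34.0	10.0	default-mode
lh_rostralmiddlefrontal	L	-32.0	42.0	22.0	fronto-parietal
lh_superiorfrontal	L	-12.0	26.0	48.0	default-mode
lh_superiorparietal	L	-24.0	-58.0	54.0	dorsal-attention
lh_superiortemporal	L	-54.0	-18.0	2.0	somato-motor
lh_supramarginal	L	-52.0	-44.0	32.0	ventral-attention
lh_frontalpole	L	-9.0	62.0	-12.0	limbic
lh_temporalpole	L	-32.0	12.0	-32.0	limbic
lh_transversetemporal	L	-44.0	-24.0	10.0	somato-motor
lh_insula	L	-36.0	-2.0	4.0	ventral-attention
rh_bankssts	R	56.0	-45.0	8.0	default-mode
rh_caudalanteriorcingulate	R	5.0	20.0	28.0	ventral-attention
rh_caudalmiddlefrontal	R	36.0	12.0	46.0	dorsal-attention
rh_cuneus	R	7.0	-80.0	26.0	visual
rh_entorhinal	R	26.0	-8.0	-32.0	limbic
rh_fusiform	R	36.0	-45.0	-20.0	visual
rh_inferiorparietal	R	42.0	-62.0	36.0	default-mode
rh_inferiortemporal	R	50.0	-32.0	-24.0	default-mode
rh_isthmuscingulate	R	7.0	-45.0	26.0	default-mode
rh_lateraloccipital	R	32.0	-86.0	2.0	visual
rh_lateralorbitofrontal	R	24.0	30.0	-16.0	limbic
rh_lingual	R	14.0	-70.0	-6.0	visual
rh_medialorbitofrontal	R	6.0	36.0	-16.0	limbic
rh_middletemporal	R	58.0	-30.0	-10.0	default-mode
rh_parahippocampal	R	26.0	-32.0	-18.0	limbic
rh_paracentral	R	8.0	-26.0	58.0	somato-motor
rh_parsopercularis	R	48.0	14.0	14.0	ventral-attention
rh_parsorbitalis	R	44.0	38.0	-10.0	fronto-parietal
rh_parstriangularis	R	46.0	30.0	8.0	fronto-parietal
rh_pericalcarine	R	10.0	-82.0	8.0	visual
rh_postcentral	R	42.0	-24.0	48.0	somato-motor
rh_posteriorcingulate	R	6.0	-22.0	38.0	default-mode
rh_precentral	R	38.0	-12.0	46.0	somato-motor
rh_precuneus	R	9.0	-58.0	40.0	default-mode
rh_rostralanteriorcingulate	R	5.0	34.0	10.0	default-mode
rh_rostralmiddlefrontal	R	32.0	42.0	22.0	fronto-parietal
rh_superiorfrontal	R	12.0	26.0	48.0	default-mode
rh_superiorparietal	R	24.0	-58.0	54.0	dorsal-attention
rh_superiortemporal	R	54.0	-18.0	2.0	somato-motor
rh_supramarginal	R	52.0	-44.0	32.0	ventral-attention
rh_frontalpole	R	9.0	62.0	-12.0	limbic
rh_temporalpole	R	32.0	12.0	-32.0	limbic
rh_transversetemporal	R	44.0	-24.0	10.0	somato-motor
rh_insula	R	36.0	-2.0	4.0	ventral-attention
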