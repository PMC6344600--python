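ref_id	family	role	source_tag
MtrA_synth	MtrA	periplasmic_MHC	synthetic:random-background stand-in with MtrA architecture (10 heme motifs, signal peptide, 333 aa)
MtoA_synth	MtoA	periplasmic_MHC	synthetic:random-background stand-in with MtoA architecture (10 heme motifs, signal peptide, 310 aa)
PioA_synth	PioA	periplasmic_MHC	synthetic:random-background stand-in with PioA architecture (10 heme motifs, signal peptide, 345 aa)
OmaB_synth	OmaB	periplasmic_MHC	synthetic:random-background stand-in with OmaB architecture (8 heme motifs, signal peptide, 300 aa)
MtrB_synth	MtrB	porin	synthetic:random-background stand-in with MtrB architecture (0 heme motifs, signal peptide, 680 aa)
MtoB_synth	MtoB	porin	synthetic:random-background stand-in with MtoB architecture (0 heme motifs, signal peptide, 760 aa)
PioB_synth	PioB	porin	synthetic:random-background stand-in with PioB architecture (0 heme motifs, signal peptide, 540 aa)
OmbB_synth	OmbB	porin	synthetic:random-background stand-in with OmbB architecture (0 heme motifs, signal peptide, 720 aa)
porin_other_synth	porin_other	porin	synthetic:random-background stand-in with porin_other architecture (0 heme motifs, signal peptide, 400 aa)
MtrC_synth	MtrC	extracellular_MHC	synthetic:random-background stand-in with MtrC architecture (10 heme motifs, signal peptide, 650 aa)
OmcB_synth	OmcB	extracellular_MHC	synthetic:random-background stand-in with OmcB architecture (12 heme motifs, signal peptide, 700 aa)
OmcE_synth	OmcE	outer_surface_MHC	synthetic:random-background stand-in with OmcE architecture (4 heme motifs, signal peptide, 180 aa)
OmcS_synth	OmcS	outer_surface_MHC	synthetic:random-background stand-in with OmcS architecture (6 heme motifs, signal peptide, 430 aa)
OmcZ_synth	OmcZ	outer_surface_MHC	synthetic:random-background stand-in with OmcZ architecture (8 heme motifs, signal peptide, 480 aa)
Cyc2_synth	Cyc2	cyc2	synthetic:random-background stand-in with Cyc2 architecture (1 heme motifs, signal peptide, 450 aa)
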