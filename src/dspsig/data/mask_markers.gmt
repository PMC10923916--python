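MACROPHAGE	CD68-mask hallmark markers	CD68	CD163	FCGR1A	CSF1R
TCELL	CD3-mask hallmark markers	CD3D	CD3E	UBASH3A	CD2	TRBC2
BCELL	CD20-mask hallmark markers	MS4A1	CD79A	CD79B	CD19	PAX5
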