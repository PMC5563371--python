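signature	monomer
DILQLGLIWK	gly
DFWNIGMVHK	ala
DVWHLSLIDK	val
DAWFLGNVVK	leu
DGFFLGVTYK	ile
DVWHFSLVDK	ser
DFWNVGMVHK	thr
DLYNLSLIWK	cys
DPRHFVMLMK	met
DAWTIAAVCK	phe
DGTITAEVAK	tyr
DALWLGGTFK	trp
DLTKVGHIGK	asp
DLTKIGEVGK	glu
DLTKLGEVGK	asn
DAWQFGLIDK	gln
DESNIGSVDK	lys
DSEDIGTVSK	arg
DSELTAEVAK	his
DVQLIAHVVK	pro
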