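target	database	accession_id	formula	mechanism
PSMA4	dgidb	IXAZOMIB	C14H19BCl2N2O4	Inhibitor
PSMA4	dgidb	BORTEZOMIB	C19H25BN4O4	Inhibitor
PSMA4	dgidb	CARFILZOMIB	C40H57N5O7	Inhibitor
PSMA4	dgidb	OPROZOMIB	C25H32N4O7S	Inhibitor
PSMA4	dgidb	MARIZOMIB	C15H20ClNO4	Inhibitor
PSMA4	dgidb	COTININE	C10H12N2O	Inhibitor
PSMA4	dgidb	IXAZOMIB CITRATE	C20H23BCl2N2O9	Inhibitor
PDK2	dgidb	AZD7545	C19H18ClF3N2O5S	Inhibitor
PDK2	dgidb	DEVIMISTAT	C22H28O2S2	Inhibitor
PDK2	dgidb	VER-246608	C28H23ClF2N4O4	Inhibitor
PDK2	dgidb	SODIUM DICHLOROACETATE	C2HCl2NaO2	Inhibitor
RPS18	dgidb	CYCLOHEXIMIDE	C15H23NO4	Inhibitor
RPS18	dgidb	EXALUREN	C19H38N4O10	Modulator
RPS18	dgidb	ATALUREN	C15H9FN2O3	Modulator
RPS18	dgidb	MT-3724	Unknown	Inhibitor
RPS18	dgidb	DORLIMOMAB ARITOX	Unknown	Inhibitor
NDUFV3	dgidb	NV-128	Unknown	Inhibitor
NDUFV3	dgidb	ME-344	C22H20O4	Inhibitor
NDUFV3	dgidb	METFORMIN HYDROCHLORIDE	C4H12ClN5	Inhibitor
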