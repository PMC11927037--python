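target	database	accession_id	formula	mechanism
PSMA4	drugbank	DB08515	C15H21NO4	Unknown
PDK2	drugbank	DB08608	C18H20F3N3O3	Unknown
PDK2	drugbank	DB08609	C19H21F3N2O4S	Unknown
PDK2	drugbank	DB08610	C20H25ClN2O2	Unknown
RPS18	drugbank	DB11638	C15H24O5	Unknown
NDUFV3	drugbank	DB00157	C21H29N7O14P2	Unknown
NDUFV3	drugbank	DB09270	C59H90O4	Cofactor
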