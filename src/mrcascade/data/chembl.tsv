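target	database	accession_id	formula	mechanism
PSMA4	chembl	CHEMBL371405	C15H20ClNO4	Inhibitor
PSMA4	chembl	CHEMBL3545432	C20H23BCl2N2O9	Inhibitor
PSMA4	chembl	CHEMBL451887	C40H57N5O7	Inhibitor
PSMA4	chembl	CHEMBL2141296	C14H19BCl2N2O4	Inhibitor
PSMA4	chembl	CHEMBL325041	C19H25BN4O4	Inhibitor
PSMA4	chembl	CHEMBL5315122	C25H35BN4O8	Inhibitor
PSMA4	chembl	CHEMBL2103884	C25H32N4O7S	Inhibitor
PDK2	chembl	CHEMBL306823	C2HCl2NaO2	Inhibitor
RPS18	chembl	CHEMBL256997	C15H9FN2O3	Modulator
RPS18	chembl	CHEMBL4297744	C19H38N4O10	Modulator
RPS18	chembl	CHEMBL123292	C15H23NO4	Inhibitor
RPS18	chembl	CHEMBL4297789	Unknown	Inhibitor
RPS18	chembl	CHEMBL2109124	Unknown	Inhibitor
NDUFV3	chembl	CHEMBL1703	C4H12ClN5	Inhibitor
NDUFV3	chembl	CHEMBL3545135	Unknown	Inhibitor
NDUFV3	chembl	CHEMBL5314386	C22H20O4	Inhibitor
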