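mesh_term	class_name	source
Chloroquine	Aminoquinolines	ATC5
Primaquine	Aminoquinolines	ATC5
Hydroxychloroquine	Aminoquinolines	ATC5
Chloroquine diphosphate	Aminoquinolines	ATC5
Azithromycin	Macrolides	ATC5
Clarithromycin	Macrolides	ATC5
Prednisolone	Corticosteroids acting locally	ATC5
Budesonide	Corticosteroids acting locally	ATC5
Prednisone	Corticosteroids acting locally	ATC5
Prednisolone phosphate	Corticosteroids acting locally	ATC5
Prednisolone acetate	Corticosteroids acting locally	ATC5
Ritonavir	Antivirals (HCV Treatment)	ATC5
Ribavirin	Antivirals (HCV Treatment)	ATC5
Sofosbuvir	Antivirals (HCV Treatment)	ATC5
Ledipasvir	Antivirals (HCV Treatment)	ATC5
Ledipasvir, Sofosbuvir drug combination	Antivirals (HCV Treatment)	ATC5
Interferons	Interferons	ATC5
Interferon-alpha	Interferons	ATC5
Interferon alpha-2	Interferons	ATC5
Interferon Type I	Interferons	ATC5
Interferon-beta	Interferons	ATC5
Interferon beta-1a	Interferons	ATC5
Ivermectin	Other dermatologicals	ATC5
Heparin	Heparin group	ATC5
Calcium heparin	Heparin group	ATC5
Tinzaparin	Heparin group	ATC5
Dalteparin	Heparin group	ATC5
Enoxaparin	Heparin group	ATC5
Losartan	ARBs, plain	ATC5
Telmisartan	ARBs, plain	ATC5
Candesartan	ARBs, plain	ATC5
Olmesartan	ARBs, plain	ATC5
Irbesartan	ARBs, plain	ATC5
Eprosartan	ARBs, plain	ATC5
Dexamethasone	Corticosteroids (local oral treatment)	ATC5
Dexamethasone acetate	Corticosteroids (local oral treatment)	ATC5
Lopinavir	Antivirals (HIV Treatment)	ATC5
Methylprednisolone	Glucocorticoids	MESHPA
Methylprednisolone Acetate	Glucocorticoids	MESHPA
Methylprednisolone Hemisuccinate	Glucocorticoids	MESHPA
Prednisolone hemisuccinate	Glucocorticoids	MESHPA
Antibodies	Immunologic Factors	MESHPA
Ascorbic Acid	Vitamins	MESHPA
Doxycycline	Tetracyclines	ATC5
IL-1Ra Protein	Antirheumatic Agents	MESHPA
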