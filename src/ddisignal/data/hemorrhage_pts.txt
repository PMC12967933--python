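# Haemorrhage preferred terms (synthetic stand-in term list).
# One MedDRA PT per line, matched case-insensitively after trimming.
# Stands in for the licensed haemorrhage SMQ; replace via configuration with
# the licensed narrow- or broad-scope list for production use.  The
# nervous-system list (ns_hemorrhage_pts.txt) is a subset of this one.
#
# --- nervous-system subset ---
Cerebral haemorrhage
Cerebral hemorrhage
Haemorrhagic stroke
Haemorrhage intracranial
Hemorrhage intracranial
Cerebral haematoma
Central nervous system haemorrhage
Central nervous system hemorrhage
Subarachnoid haemorrhage
Subarachnoid hemorrhage
Cerebellar haematoma
Cerebellar haemorrhage
Intraventricular haemorrhage
Brain stem haemorrhage
Subdural haematoma
Subdural haemorrhage
Extradural haematoma
# --- other haemorrhage PTs ---
Gastrointestinal haemorrhage
Gastrointestinal hemorrhage
Upper gastrointestinal haemorrhage
Lower gastrointestinal haemorrhage
Rectal haemorrhage
Anal haemorrhage
Melaena
Haematemesis
Haematochezia
Epistaxis
Haemoptysis
Haematuria
Urogenital haemorrhage
Vaginal haemorrhage
Uterine haemorrhage
Menorrhagia
Metrorrhagia
Haemorrhage
Haemorrhagic anaemia
Haemorrhagic diathesis
Haematoma
Contusion
Ecchymosis
Petechiae
Purpura
Increased tendency to bruise
Gingival bleeding
Mouth haemorrhage
Conjunctival haemorrhage
Eye haemorrhage
Retinal haemorrhage
Vitreous haemorrhage
Haemorrhoidal haemorrhage
Post procedural haemorrhage
Procedural haemorrhage
Wound haemorrhage
Injection site haemorrhage
Pericardial haemorrhage
Pulmonary haemorrhage
Retroperitoneal haemorrhage
Splenic haemorrhage
Hepatic haemorrhage
Renal haemorrhage
Adrenal haemorrhage
Blood loss anaemia
Blood urine present
Occult blood positive
Haemorrhagic shock
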