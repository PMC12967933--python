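# Nervous-system haemorrhage preferred terms (synthetic stand-in term list).
# One MedDRA PT per line, matched case-insensitively after trimming.
# The licensed MedDRA HLGT "Central nervous system vascular disorders" cannot
# be redistributed; this list covers the common haemorrhagic PTs under it and
# can be replaced by the licensed list via configuration.
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
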