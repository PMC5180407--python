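# diagnosis	disease_group  (lookup applied to fixture diagnoses)
CML	hematologic
AML	hematologic
ALL	hematologic
B-ALL	hematologic
T-ALL	hematologic
AMKL	hematologic
MDS	hematologic
HLH	hematologic
AML changed to JMML	hematologic
Hepatic rhabdoid tumor	solid
Osteosarcoma	solid
Nephroblastomatosis	solid
Pleomorphic xanthoastrocytoma	solid
Neuroblastoma	solid
Rhabdomyosarcoma	solid
Glioblastoma multiforme	solid
Medulloblastoma	solid
Glioma	solid
Adrenocortical carcinoma	solid
Congenital fibrosarcoma	solid
Inflammatory myofibroblastic tumor	solid
Renal cell carcinoma	solid
Pleuropulmonaryblastoma	solid
Ewing sarcoma	solid
Alveolar soft part sarcoma	solid
Undifferentiated sarcoma	solid
Ependymoma	solid
Hepatoblastoma	solid
ATRT	solid
Small round blue cell tumor	solid
Hepatocellular carcinoma	solid
Pineoblastoma	solid
Poorly differentiated carcinoma with focal neuroendocrine differentiation	solid
Nested stromal epithelial tumor of the liver	solid
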