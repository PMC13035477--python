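ligand,receptor,class
CXCL13,CXCR5,homeostatic
CXCL12,CXCR4,homeostatic
CXCL12,ACKR3,homeostatic
CCL19,CCR7,homeostatic
CCL19,ACKR4,homeostatic
CCL21,CCR7,homeostatic
CCL21,ACKR4,homeostatic
CXCL9,CXCR3,inflammatory
CXCL10,CXCR3,inflammatory
CXCL11,CXCR3,inflammatory
CXCL11,ACKR1,inflammatory
CCL2,CCR2,other
CCL3,CCR1,other
CCL3,CCR5,other
CCL4,CCR5,other
CCL5,CCR1,other
CCL5,CCR3,other
CCL5,CCR5,other
CCL17,CCR4,other
CCL20,CCR6,other
CCL22,CCR4,other
CXCL8,CXCR1,other
CXCL8,CXCR2,other
CXCL16,CXCR6,other
CX3CL1,CX3CR1,other
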