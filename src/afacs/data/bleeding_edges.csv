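from,to,hr,source
TAT-warfarin,DAPT-clopidogrel,2.2,Danish nationwide registry (adjusted early bleeding)
DAT-dabigatran-110,TAT-warfarin,0.52,RE-DUAL PCI
DAT-dabigatran-150,TAT-warfarin,0.72,RE-DUAL PCI
DAT-rivaroxaban-15,TAT-warfarin,0.59,PIONEER AF-PCI
DAT-apixaban-5-bid,TAT-warfarin,0.39,AUGUSTUS
DAPT-ticagrelor,DAPT-clopidogrel,1.05,PLATO
DAPT-prasugrel,DAPT-clopidogrel,1.31,TRITON-TIMI 38
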