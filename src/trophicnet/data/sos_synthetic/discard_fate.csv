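fleet,DC,SPOM,BD
1.GNS,1.0,0.0,0.0
1.LLD,1.0,0.0,0.0
1.LTL,1.0,0.0,0.0
1.LH,1.0,0.0,0.0
1.MIS,1.0,0.0,0.0
1.PS,1.0,0.0,0.0
2.FPO,1.0,0.0,0.0
2.GNS,1.0,0.0,0.0
2.LLD,1.0,0.0,0.0
2.MIS,1.0,0.0,0.0
2.OTB_D,1.0,0.0,0.0
2.OTB_DWS,1.0,0.0,0.0
2.OTB_MDD,1.0,0.0,0.0
2.OTM,1.0,0.0,0.0
2.PTM,1.0,0.0,0.0
2.PS,1.0,0.0,0.0
3.OTM,1.0,0.0,0.0
3.OTB_MDDW,1.0,0.0,0.0
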