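# Published per-participant demographics of the ten-participant breast-cancer-survivor
# home-monitoring validation cohort (fixture v1). QuickDASH: 0-100, >15 = UL dysfunction.
participant,age_years,bmi,operated_side,surgery,adjuvant_treatment,quickdash
P_001,44,31.87,R,ME+SN,TAM,0
P_002,48,19.69,L,ME+SN,Adj.CT+TAM,9.1
P_003,50,25.09,R,BCS+SN,Adj.RT+TAM,38.6
P_004,53,29.29,L,ME+SN,,4.5
P_005,52,26.29,L,BCS+SN,Adj.RT+TAM,13.6
P_006,45,24.6,L,ME+ALND,Neo-adj.CT+Adj.RT+AI,11.4
P_007,52,27.88,R,ME+ALND,Neo-adj.CT+Adj.RT,15.9
P_008,43,23.52,R,ME+SN,TAM,0
P_009,65,28.37,R,BCS+SN,Adj.RT+AI,15.9
P_010,72,19.83,L,BCS+ALND,Neo-adj.CT+Adj.RT+AI,11.4
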