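# event_id:int64	peak_sample:int64	trough_sample:int64	peak_s:float64	frequency:float64	amplitude:float64	duration:float64
event_id	peak_sample	trough_sample	peak_s	frequency	amplitude	duration
0	5521	5514	2.2084	82.64442168456466	3.1744999658616915	0.5503783629581965
1	11111	11108	4.4444	210.12323827204358	4.740289695151073	1.5944831696449162
2	17256	17253	6.9024	226.04089236443548	4.263414216486129	0.7634834309038385
3	22671	22667	9.0684	177.06172412274879	1.0109540006805924	1.7947683835248298
4	29850	29847	11.94	196.71944975743975	4.429617106350277	1.3121918303736375
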