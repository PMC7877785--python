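loop_len	dg_centikcal
3	540
4	560
5	570
6	540
7	600
8	550
9	640
10	650
11	660
12	670
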