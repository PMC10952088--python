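# Synthetic example of a descriptor reference table (NOT experimental data).
# Linear temperature trends with realistic signs/magnitudes for liquid water,
# for demonstrating and testing the 298 K rescaling only.
temperature_K,r_max1,g_max1,r_min1,g_min1
278,2.795,2.75,3.32,0.80
288,2.800,2.65,3.34,0.83
298,2.805,2.55,3.36,0.86
308,2.810,2.45,3.38,0.89
318,2.815,2.35,3.40,0.92
328,2.820,2.25,3.42,0.95
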