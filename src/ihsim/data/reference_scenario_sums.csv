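aggregate,baseline_sum,last5_sum,medicated_only_sum,p
Anxiety,-5264.94,-7695.29,-2127.76,0.111
Depression,-1468.65,-1936.36,-519.98,0.345
Sleep inertia,-23785.71,-31467.42,-7561.71,0.48
Work and social impairment,-19854.40,-22906.08,-2865.86,0.004
Sleepiness,-12983.30,-17127.30,-3760.46,0.028
Fatigue,-5885.17,-9196.22,-3168.03,0.345
Naps,19689.76,26442.19,5941.81,0.028
Nocturnal sleep,17099.39,22418.76,4535.73,0.008
Other psychiatric disorders,-1502.53,-1954.41,-550.40,0.345
Somatic pathologies,-4773.05,-5924.73,-1077.70,0.004
Methylphenidate effect,1109.83,1768.80,782.93,0.421
Modafinil effect,1254.81,2244.32,1014.49,0.5
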