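cycle_day,non-survivor,control,survivor
-11,-1.20,-1.53,-1.66
-10,-1.31,-1.47,-1.56
-9,-1.36,-1.58,-1.56
-8,-1.01,-1.49,-1.63
-7,-1.29,-1.42,-1.38
-6,-1.21,-1.44,-1.71
-5,-1.29,-1.39,-1.83
-4,-1.28,-1.32,-1.54
-3,-1.42,-1.34,-1.41
-2,-1.11,-1.38,-1.64
-1,-1.21,-1.29,-2.22
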