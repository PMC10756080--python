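name,G,S,lambda_min,lambda_max,n_channels,harmonic
collagen_I,0.6016121777067597,0.6442257932425022,423.0,723.0,30,1
collagen_II,0.46856507091428595,0.7104425752043826,423.0,723.0,30,1
collagen_III,0.40711897344285514,0.7376098827051761,423.0,723.0,30,1
collagen_IV,0.25488385267615443,0.7705095049759259,423.0,723.0,30,1
elastin,0.0335795348918798,0.7923244510567846,423.0,723.0,30,1
nadh,0.5262949319351178,0.6919318421428298,423.0,723.0,30,1
fad,-0.5604185938227952,0.572112714904024,423.0,723.0,30,1
melanin,-0.2503541730972452,-0.5846624828051071,423.0,723.0,30,1
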