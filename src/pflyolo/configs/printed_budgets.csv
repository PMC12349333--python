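# Published variant-level budgets (ablation table of the source study).
# params_million at 2 decimals, flops_g at 1 decimal, size_mb as printed.
# head_* rows are the layer-22 anchors (exact params; FLOPs in G at 640x640).
# version: 1
variant,params_million,flops_g,size_mb
baseline,3.02,8.1,6.0
esppf,2.86,8.0,5.7
esppf+ehconv,2.30,6.9,4.6
esppf+rc2f,2.27,7.0,4.5
esppf+pfdetect,2.16,5.4,4.3
esppf+ehconv+rc2f,1.71,5.9,3.5
esppf+ehconv+pfdetect,1.60,4.3,3.3
esppf+rc2f+pfdetect,1.57,4.4,3.2
esppf+ehconv+rc2f+pfdetect,1.01,3.3,2.1
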