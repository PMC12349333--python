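# Per-layer reference budgets at input 640x640, nc=60.
# Provenance: closed-form accounting of the canonical baseline wiring and the
# calibrated lightweight configuration; totals and layer-22 anchors agree with
# the published budget table to its printed precision (see printed_budgets.csv).
# version: 1
model,index,kind,params,flops
baseline,0,conv,464,88473600
baseline,1,conv,4672,235929600
baseline,2,c2f,7360,367001600
baseline,3,conv,18560,235929600
baseline,4,c2f,49664,629145600
baseline,5,conv,73984,235929600
baseline,6,c2f,197632,629145600
baseline,7,conv,295424,235929600
baseline,8,c2f,460288,367001600
baseline,9,sppf,164608,131072000
baseline,10,upsample,0,0
baseline,11,concat,0,0
baseline,12,c2f,148224,471859200
baseline,13,upsample,0,0
baseline,14,concat,0,0
baseline,15,c2f,37248,471859200
baseline,16,conv,36992,117964800
baseline,17,concat,0,0
baseline,18,c2f,123648,393216000
baseline,19,conv,147712,117964800
baseline,20,concat,0,0
baseline,21,c2f,493056,393216000
baseline,22,detect,763012,3023462400
pfl-yolo,0,ehconv,467,88473696
pfl-yolo,1,ehconv,643,29491392
pfl-yolo,2,rc2f,2413,113356992
pfl-yolo,3,ehconv,1283,14745984
pfl-yolo,4,rc2f,9251,113357184
pfl-yolo,5,ehconv,2565,7374080
pfl-yolo,6,rc2f,36213,113358080
pfl-yolo,7,ehconv,5125,3688960
pfl-yolo,8,rc2f,143269,113359360
pfl-yolo,9,esppf,3845,2460160
pfl-yolo,10,upsample,0,0
pfl-yolo,11,concat,0,0
pfl-yolo,12,rc2f,283797,902247680
pfl-yolo,13,upsample,0,0
pfl-yolo,14,concat,0,0
pfl-yolo,15,rc2f,71411,902246784
pfl-yolo,16,ehconv,2435,7373184
pfl-yolo,17,concat,0,0
pfl-yolo,18,rc2f,76149,240308480
pfl-yolo,19,ehconv,4869,3687680
pfl-yolo,20,concat,0,0
pfl-yolo,21,rc2f,302485,240309760
pfl-yolo,22,pfdetect,59999,405850464
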