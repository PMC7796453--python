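# Published per-experiment segmentation accuracies (best CNN experiments):
# potential segmentation error, number-of-segmentation ratio and their
# Euclidean combination ED2, printed at 4 decimals.
experiment,train,test,pse,nsr,ed2
1.1.C,UAV,UAV,0.0532,0.1290,0.1396
1.2.C,UAV,UAV,0.0512,0.0967,0.1095
2.1.C,Airborne,Airborne,0.0408,0.0645,0.0763
2.2.C,Airborne,Airborne,0.0589,0.0645,0.0873
3.1.B,GE,GE,0.0414,0.0645,0.0767
3.2.B,GE,UAV,0.0501,0.0645,0.0816
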