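model,dataset,mode,avg_iou
UNet,blastocyst,C,0.8643
UNet,blastocyst,L,0.7726
UNet,blastocyst,S,0.8593
UNet,ham10k,C,0.8672
UNet,ham10k,L,0.8320
UNet,ham10k,S,0.8640
UNet,kvasir_seg,C,0.8271
UNet,kvasir_seg,L,0.6946
UNet,kvasir_seg,S,0.8042
SegNet,blastocyst,C,0.8475
SegNet,blastocyst,L,0.7416
SegNet,blastocyst,S,0.8475
SegNet,ham10k,C,0.8426
SegNet,ham10k,L,0.7773
SegNet,ham10k,S,0.8620
SegNet,kvasir_seg,C,0.7337
SegNet,kvasir_seg,L,0.5713
SegNet,kvasir_seg,S,0.7669
SUNet,blastocyst,C,0.8487
SUNet,blastocyst,L,0.7566
SUNet,blastocyst,S,0.8504
SUNet,ham10k,C,0.8679
SUNet,ham10k,L,0.8241
SUNet,ham10k,S,0.8539
SUNet,kvasir_seg,C,0.7280
SUNet,kvasir_seg,L,0.6006
SUNet,kvasir_seg,S,0.7233
DeepLabV3,blastocyst,C,0.8768
DeepLabV3,blastocyst,L,0.8016
DeepLabV3,blastocyst,S,0.8369
DeepLabV3,ham10k,C,0.8699
DeepLabV3,ham10k,L,0.7715
DeepLabV3,ham10k,S,0.8696
DeepLabV3,kvasir_seg,C,0.8438
DeepLabV3,kvasir_seg,L,0.7715
DeepLabV3,kvasir_seg,S,0.8262
DeepLabV3+,blastocyst,C,0.8774
DeepLabV3+,blastocyst,L,0.6834
DeepLabV3+,blastocyst,S,0.8591
DeepLabV3+,ham10k,C,0.8715
DeepLabV3+,ham10k,L,0.8311
DeepLabV3+,ham10k,S,0.8262
DeepLabV3+,kvasir_seg,C,0.8264
DeepLabV3+,kvasir_seg,L,0.6965
DeepLabV3+,kvasir_seg,S,0.8278
RefineNet,blastocyst,C,0.7881
RefineNet,blastocyst,L,0.6948
RefineNet,blastocyst,S,0.8181
RefineNet,ham10k,C,0.8584
RefineNet,ham10k,L,0.8161
RefineNet,ham10k,S,0.8403
RefineNet,kvasir_seg,C,0.7083
RefineNet,kvasir_seg,L,0.6669
RefineNet,kvasir_seg,S,0.7652
Attention UNet,blastocyst,C,0.8673
Attention UNet,blastocyst,L,0.6990
Attention UNet,blastocyst,S,0.8605
Attention UNet,ham10k,C,0.8654
Attention UNet,ham10k,L,0.8241
Attention UNet,ham10k,S,0.8699
Attention UNet,kvasir_seg,C,0.8236
Attention UNet,kvasir_seg,L,0.6991
Attention UNet,kvasir_seg,S,0.7961
Swin-UNet,blastocyst,C,0.8074
Swin-UNet,blastocyst,L,0.6283
Swin-UNet,blastocyst,S,0.8142
Swin-UNet,ham10k,C,0.8492
Swin-UNet,ham10k,L,0.7768
Swin-UNet,ham10k,S,0.8478
Swin-UNet,kvasir_seg,C,0.7871
Swin-UNet,kvasir_seg,L,0.5483
Swin-UNet,kvasir_seg,S,0.6642
CGNet,blastocyst,C,0.8433
CGNet,blastocyst,L,0.7287
CGNet,blastocyst,S,0.7891
CGNet,ham10k,C,0.8728
CGNet,ham10k,L,0.8382
CGNet,ham10k,S,0.8490
CGNet,kvasir_seg,C,0.8354
CGNet,kvasir_seg,L,0.6868
CGNet,kvasir_seg,S,0.8110
DUCK-Net,blastocyst,C,0.8725
DUCK-Net,blastocyst,L,0.7994
DUCK-Net,blastocyst,S,0.8321
DUCK-Net,ham10k,C,0.8652
DUCK-Net,ham10k,L,0.8389
DUCK-Net,ham10k,S,0.8600
DUCK-Net,kvasir_seg,C,0.8824
DUCK-Net,kvasir_seg,L,0.7778
DUCK-Net,kvasir_seg,S,0.7800
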