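band,source,target,auc
delta,F7,F8,0.756
delta,FC5,F8,0.717
delta,O2,F8,0.713
delta,O2,FC6,0.695
delta,F7,FC6,0.695
delta,F8,F7,0.692
delta,AF3,FC6,0.687
delta,O1,FC6,0.686
delta,AF3,F8,0.684
delta,P8,F8,0.679
delta,T7,F8,0.679
delta,FC6,F8,0.677
delta,O1,F8,0.674
delta,FC6,F7,0.673
delta,T8,F8,0.669
delta,P8,FC6,0.663
delta,P7,F8,0.662
delta,AF4,FC6,0.661
delta,F3,F8,0.660
delta,AF4,F8,0.655
delta,T8,F7,0.653
delta,P7,FC6,0.653
delta,O2,F7,0.652
delta,F4,F8,0.651
delta,O1,F7,0.650
delta,F3,FC6,0.647
delta,T7,FC6,0.646
delta,F3,F7,0.644
delta,T8,FC6,0.642
delta,P8,F7,0.639
theta,F7,F8,0.728
theta,O2,F8,0.716
theta,AF3,F8,0.697
theta,P8,F8,0.691
theta,O2,FC6,0.690
theta,O1,F8,0.688
theta,AF4,F8,0.677
theta,F8,F7,0.675
theta,AF3,FC6,0.672
theta,FC5,F8,0.664
theta,O2,F7,0.662
theta,P8,FC6,0.659
theta,F3,F8,0.657
theta,P7,F8,0.656
theta,T7,F8,0.654
theta,O1,FC6,0.653
theta,AF4,FC6,0.651
theta,AF3,F7,0.649
theta,T8,F8,0.646
theta,F7,FC6,0.644
theta,AF4,F7,0.643
theta,O1,F7,0.643
theta,O2,FC5,0.642
theta,P8,F7,0.640
theta,F4,F8,0.640
theta,F3,F7,0.637
theta,P7,F7,0.633
theta,FC6,F8,0.626
theta,T8,F7,0.625
theta,P7,FC6,0.621
alpha,FC5,O2,0.675
alpha,FC6,O1,0.663
alpha,FC6,O2,0.663
alpha,F7,F8,0.658
alpha,FC6,P8,0.654
alpha,T8,O2,0.652
alpha,T8,P8,0.647
alpha,FC5,P8,0.645
alpha,T7,O2,0.642
alpha,AF3,F8,0.639
alpha,O1,O2,0.635
alpha,F4,P8,0.635
alpha,FC6,P7,0.633
alpha,F7,O2,0.633
alpha,T8,O1,0.633
alpha,O1,P8,0.631
alpha,P7,O2,0.630
alpha,AF4,F8,0.628
alpha,F4,O2,0.626
alpha,FC5,O1,0.624
alpha,F3,P8,0.623
alpha,F8,O1,0.623
alpha,O2,P8,0.622
alpha,F4,O1,0.621
alpha,P7,O1,0.620
alpha,F3,O2,0.620
alpha,F8,O2,0.619
alpha,O1,O1,0.619
alpha,T7,O1,0.617
alpha,F8,F7,0.616
beta,P8,F8,0.670
beta,AF4,F8,0.666
beta,O2,F8,0.666
beta,T8,P8,0.662
beta,T8,O2,0.655
beta,O2,FC6,0.654
beta,AF3,F8,0.652
beta,F7,F8,0.643
beta,F3,F8,0.643
beta,FC6,O2,0.642
beta,T7,O2,0.640
beta,P7,F8,0.638
beta,O1,FC6,0.638
beta,O1,F8,0.636
beta,P8,F7,0.636
beta,FC6,P8,0.636
beta,P8,FC6,0.636
beta,T7,P8,0.632
beta,O2,F7,0.632
beta,F3,F7,0.630
beta,AF3,F7,0.626
beta,FC6,O1,0.626
beta,P7,FC6,0.624
beta,O1,F7,0.622
beta,FC5,O2,0.621
beta,FC5,P8,0.621
beta,F3,FC6,0.620
beta,P7,F7,0.620
beta,AF3,FC6,0.619
beta,O2,FC5,0.616
gamma,O2,F8,0.688
gamma,P8,F8,0.670
gamma,O2,FC6,0.669
gamma,O1,FC6,0.661
gamma,O2,F7,0.660
gamma,O1,F8,0.658
gamma,T8,P8,0.657
gamma,P8,FC6,0.652
gamma,FC6,P8,0.648
gamma,O2,FC5,0.642
gamma,P8,F7,0.642
gamma,P7,FC6,0.641
gamma,AF4,F8,0.638
gamma,P7,F8,0.637
gamma,O1,F7,0.636
gamma,P8,FC5,0.634
gamma,F7,P8,0.633
gamma,T8,O2,0.628
gamma,O1,FC5,0.627
gamma,F7,O2,0.626
gamma,AF4,FC6,0.624
gamma,FC6,O2,0.624
gamma,F3,F8,0.623
gamma,F3,FC6,0.618
gamma,F8,P8,0.618
gamma,P7,F7,0.614
gamma,AF4,F7,0.611
gamma,FC6,O1,0.609
gamma,FC6,F4,0.609
gamma,FC6,AF4,0.609
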