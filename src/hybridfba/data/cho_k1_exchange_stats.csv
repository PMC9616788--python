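species,mean,sd,cv_pct
mu,2.82e-02,3.36e-03,11.9
Glc,-3.84e-01,1.05e-01,27.3
Lac,2.56e-01,1.41e-01,55.1
Gln,-7.37e-02,3.31e-02,44.9
Glu,8.90e-03,4.84e-03,54.4
NH4,5.92e-02,2.82e-02,47.6
Pyr,2.04e-03,2.00e-02,980
Glyc,5.63e-03,1.57e-03,27.9
Cit,-9.41e-04,1.96e-03,208
Ala,9.47e-02,1.21e-02,12.8
Arg,-1.09e-02,4.81e-03,44.1
Asn,-7.13e-02,1.19e-02,16.7
Asp,3.11e-03,5.30e-03,170
LCystin,-2.74e-03,2.64e-03,96.4
Gly,2.49e-02,4.37e-03,17.6
His,-5.62e-03,1.90e-03,33.8
Ile,-1.37e-02,5.42e-03,39.6
Leu,-2.13e-02,6.59e-03,30.9
Lys,-9.82e-03,6.15e-03,62.6
Met,-4.77e-03,4.28e-03,89.7
Phe,-6.41e-03,3.13e-03,48.8
Pro,-5.00e-03,6.36e-03,127
Ser,-3.69e-02,9.66e-03,26.2
Thr,-1.03e-02,5.76e-03,55.9
Trp,-3.68e-03,4.96e-03,135
Tyr,-4.25e-03,3.59e-03,84.5
Val,-1.45e-02,6.64e-03,45.8
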