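model,RMSD,prime_gfactor,prime_energy,yasara_zscore,yasara_energy,dope
ver01,2.998,-9.323,-733,-0.771,-5438,-5.99
ver02,2.277,-9.357,-669,-0.132,-6294,-6.32
ver03,1.803,-9.561,-657,-0.090,-6372,-6.36
ver04,1.314,-10.02,-506,-0.304,-5426,-6.52
ver05,1.305,-9.391,-439,-0.458,-5433,-6.49
ver06,1.318,-9.142,-492,-0.584,-5700,-6.53
ver07,1.036,-8.249,-528,-0.034,-6261,-6.44
ver08,0.785,-8.883,-547,0.005,-6706,-6.73
ver09,1.585,-7.954,-533,0.086,-6781,-6.79
ver10,1.504,-8.561,-529,0.182,-6883,-6.81
ver11,1.942,-10.67,-484,-0.980,-5009,-6.37
ver12,2.602,-10.00,-505,-1.065,-4588,-6.18
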