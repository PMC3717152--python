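model,RMSD,prime_gfactor,prime_energy,yasara_zscore,yasara_energy,dope
ver01,5.611,-8.161,-10858,-1.602,-101125,-40964
ver02,4.366,-7.599,-11284,-0.487,-115209,-43018
ver03,3.799,-7.823,-9055,-0.836,-109204,-41671
ver04,3.538,-7.355,-8913,0.284,-121882,-42550
ver05,3.861,-7.936,-8252,-1.580,-100605,-40929
ver06,3.504,-7.574,-10213,-0.397,-115606,-41124
ver07,2.985,-8.219,-10842,-0.521,-111144,-41559
ver08,2.824,-6.558,-10494,0.285,-124144,-42602
ver09,2.948,-7.425,-10572,0.193,-124519,-42994
ver10,2.958,-7.362,-10515,0.236,-124578,-42883
ver11,3.141,-7.952,-9693,-1.212,-100836,-38448
ver12,5.581,-8.057,-10094,-1.792,-94563,-38189
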