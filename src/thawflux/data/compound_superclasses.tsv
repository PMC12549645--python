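compound	superclass
Acetophenone	Benzenoids
Benzaldehyde	Benzenoids
Biphenyl	Benzenoids
Butylated Hydroxytoluene	Benzenoids
Decanal	Lipids and lipid-like molecules
Dodecanal	Lipids and lipid-like molecules
Dodecane	Hydrocarbons
Hentriacontane	Hydrocarbons
Methyl Alcohol	Organic oxygen compounds
Nonanoic acid	Lipids and lipid-like molecules
o-Xylene	Benzenoids
Octanoic acid	Lipids and lipid-like molecules
p-Xylene	Benzenoids
Pentanoic acid	Lipids and lipid-like molecules
Phenol	Benzenoids
Tridecane	Hydrocarbons
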