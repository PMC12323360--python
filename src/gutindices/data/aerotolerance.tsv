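taxon	level	category	citation
Escherichia	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Shigella	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Salmonella	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Klebsiella	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Enterobacter	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Citrobacter	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Proteus	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Serratia	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Morganella	genus	aerotolerant	facultative anaerobe (Enterobacteriaceae)
Haemophilus	genus	aerotolerant	facultative anaerobe
Pseudomonas	genus	aerotolerant	aerobe
Acinetobacter	genus	aerotolerant	aerobe
Staphylococcus	genus	aerotolerant	facultative anaerobe
Streptococcus	genus	aerotolerant	facultative anaerobe; includes microaerophilic members, counted aerotolerant here
Enterococcus	genus	aerotolerant	facultative anaerobe
Lactobacillus	genus	aerotolerant	aerotolerant anaerobe
Lactococcus	genus	aerotolerant	facultative anaerobe
Bacillus	genus	aerotolerant	aerobe or facultative anaerobe
Corynebacterium	genus	aerotolerant	aerobe or facultative anaerobe
Bacteroides	genus	strict_anaerobe	obligate anaerobe
Parabacteroides	genus	strict_anaerobe	obligate anaerobe
Prevotella	genus	strict_anaerobe	obligate anaerobe
Alistipes	genus	strict_anaerobe	obligate anaerobe
Faecalibacterium	genus	strict_anaerobe	obligate anaerobe
Roseburia	genus	strict_anaerobe	obligate anaerobe
Ruminococcus	genus	strict_anaerobe	obligate anaerobe
Coprococcus	genus	strict_anaerobe	obligate anaerobe
Dorea	genus	strict_anaerobe	obligate anaerobe
Blautia	genus	strict_anaerobe	obligate anaerobe
Eubacterium	genus	strict_anaerobe	obligate anaerobe
Anaerostipes	genus	strict_anaerobe	obligate anaerobe
Subdoligranulum	genus	strict_anaerobe	obligate anaerobe
Oscillibacter	genus	strict_anaerobe	obligate anaerobe
Butyrivibrio	genus	strict_anaerobe	obligate anaerobe
Dialister	genus	strict_anaerobe	obligate anaerobe
Veillonella	genus	strict_anaerobe	obligate anaerobe
Megasphaera	genus	strict_anaerobe	obligate anaerobe
Phascolarctobacterium	genus	strict_anaerobe	obligate anaerobe
Desulfovibrio	genus	strict_anaerobe	obligate anaerobe
Fusobacterium	genus	strict_anaerobe	obligate anaerobe
Clostridium	genus	strict_anaerobe	obligate anaerobe
Akkermansia	genus	strict_anaerobe	obligate anaerobe
Christensenella	genus	strict_anaerobe	obligate anaerobe
Methanobrevibacter	genus	strict_anaerobe	obligate anaerobe (methanogenic archaeon)
Bifidobacterium longum	species	strict_anaerobe	Bifidobacterium handled at species level
Bifidobacterium adolescentis	species	strict_anaerobe	Bifidobacterium handled at species level
Bifidobacterium bifidum	species	strict_anaerobe	Bifidobacterium handled at species level
Bifidobacterium breve	species	strict_anaerobe	Bifidobacterium handled at species level
Bifidobacterium pseudocatenulatum	species	strict_anaerobe	Bifidobacterium handled at species level
Bifidobacterium catenulatum	species	strict_anaerobe	Bifidobacterium handled at species level
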