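# Miniature taxon -> putative-function rules for freshwater phytotelm
# prokaryote communities. Format: "> group" header, then one pattern per
# indented line; a pattern is a semicolon-separated rank path matched as
# a contiguous run anywhere in the lineage (case-insensitive).
# This file is a small curated stand-in written for this package, not an
# excerpt of any published database.

> chemoheterotrophy
    Pedosphaeraceae
    Chthoniobacteraceae
    Pirellulaceae
    Acidobacteriaceae
    Xanthobacteraceae
    Enterobacteriaceae
    Clostridiaceae
    Bacteroidaceae
    Rhodobacteraceae
    Comamonadaceae
    Microbacteriaceae

> fermentation
    Clostridiaceae
    Bacteroidaceae
    Enterobacteriaceae
    Lactobacillaceae

> nitrate_reduction
    Enterobacteriaceae
    Paracoccus
    Pseudomonadaceae

> nitrogen_fixation
    Xanthobacter
    Rhizobiaceae
    Nostocaceae
    Azotobacter

> nitrification
    Nitrosomonadaceae
    Nitrospiraceae

> ureolysis
    Sporosarcina
    Ureibacillus

> methanogenesis
    Methanobacteriaceae
    Methanomicrobiaceae
    Methanosarcinaceae

> methanotrophy
    Methylococcaceae
    Methylocystaceae

> sulfate_respiration
    Desulfovibrionaceae
    Desulfobacteraceae

> sulfur_oxidation
    Sulfurimonas
    Chromatiaceae
    Thiobacillus

> hydrogen_oxidation
    Hydrogenophaga
    Hydrogenophilaceae

> phototrophy
    Cyanobacteria
    Chromatiaceae
    Chlorobiaceae

> photoheterotrophy
    Rhodospirillaceae
    Rhodopseudomonas

> animal_parasitism
    Legionellaceae
    Coxiellaceae

> intracellular_parasites
    Chlamydiae
    Rickettsiaceae

> cellulolysis
    Fibrobacteraceae
    Cellulomonadaceae

> predatory_bacteria
    Bdellovibrionaceae
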