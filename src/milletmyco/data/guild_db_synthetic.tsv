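taxon	taxonomicLevel	trophicMode	guild	confidenceRanking	growthForm
Fusarium	genus	Pathotroph-Saprotroph-Symbiotroph	Plant Pathogen-Soil Saprotroph-Wood Saprotroph-Endophyte	Highly Probable	Microfungus
Penicillium	genus	Saprotroph	Dung Saprotroph-Undefined Saprotroph-Wood Saprotroph	Highly Probable	Microfungus
Curvularia	genus	Pathotroph	Plant Pathogen	Probable	Microfungus
Bipolaris	genus	Pathotroph	Plant Pathogen	Probable	Microfungus
Cochliobolus	genus	Pathotroph	Plant Pathogen	Highly Probable	Microfungus
Helminthosporium	genus	Pathotroph	Fungal Parasite-Plant Pathogen	Probable	Microfungus
Paecilomyces	genus	Saprotroph-Symbiotroph	Clavicipitaceous Endophyte-Undefined Saprotroph	Probable	Microfungus
Chaetomium	genus	Saprotroph	Dung Saprotroph-Soil Saprotroph-Wood Saprotroph	Probable	Microfungus
Talaromyces	genus	Saprotroph	Undefined Saprotroph	Highly Probable	Microfungus
Mortierella	genus	Saprotroph	Soil Saprotroph	Highly Probable	Microfungus
Preussia	genus	Saprotroph	Dung Saprotroph	Probable	Microfungus
Schizothecium	genus	Saprotroph	Dung Saprotroph	Probable	Microfungus
Coprinopsis	genus	Saprotroph	Dung Saprotroph-Undefined Saprotroph	Highly Probable	Agaricoid
Glomus	genus	Symbiotroph	Arbuscular Mycorrhizal	Highly Probable	Glomeromycete
Rhizophagus	genus	Symbiotroph	Arbuscular Mycorrhizal	Highly Probable	Glomeromycete
Funneliformis	genus	Symbiotroph	Arbuscular Mycorrhizal	Highly Probable	Glomeromycete
Serendipita	genus	Symbiotroph	Endophyte-Ectomycorrhizal	Probable	Microfungus
Tuber	genus	Symbiotroph	Ectomycorrhizal	Highly Probable	Hypogeous
Phoma	genus	Pathotroph-Saprotroph	Plant Pathogen-Undefined Saprotroph	Probable	Microfungus
Stemphylium	genus	Pathotroph-Saprotroph	Plant Pathogen-Undefined Saprotroph	Probable	Microfungus
Macrophomina	genus	Pathotroph-Saprotroph	Plant Pathogen-Wood Saprotroph	Highly Probable	Microfungus
Setophoma	genus	Pathotroph-Saprotroph	Plant Pathogen-Soil Saprotroph	Probable	Microfungus
Pyrenophora	genus	Pathotroph-Saprotroph	Plant Pathogen-Undefined Saprotroph	Probable	Microfungus
Moesziomyces	genus	Pathotroph-Symbiotroph	Plant Pathogen-Epiphyte	Probable	Yeast
Ustilago	genus	Pathotroph-Symbiotroph	Plant Pathogen-Endophyte	Probable	Smut
Exophiala	genus	Saprotroph-Symbiotroph	Soil Saprotroph-Root Associated Biotroph	Probable	Microfungus
Periconia	genus	Saprotroph-Symbiotroph	Undefined Saprotroph-Endophyte	Probable	Microfungus
Cladophialophora	genus	Saprotroph-Symbiotroph	Soil Saprotroph-Endophyte	Probable	Microfungus
Alternaria	genus	Pathotroph-Saprotroph-Symbiotroph	Plant Pathogen-Soil Saprotroph-Endophyte	Highly Probable	Microfungus
Cladosporium	genus	Pathotroph-Saprotroph-Symbiotroph	Plant Pathogen-Undefined Saprotroph-Endophyte	Probable	Microfungus
Rhizoctonia	genus	Pathotroph-Saprotroph-Symbiotroph	Plant Pathogen-Soil Saprotroph-Orchid Mycorrhizal	Highly Probable	Microfungus
Colletotrichum	genus	Pathotroph-Saprotroph-Symbiotroph	Plant Pathogen-Undefined Saprotroph-Endophyte	Probable	Microfungus
Nigrospora	genus	Pathotroph-Saprotroph-Symbiotroph	Plant Pathogen-Undefined Saprotroph-Endophyte	Probable	Microfungus
Epicoccum	genus	Pathotroph-Saprotroph-Symbiotroph	Plant Pathogen-Undefined Saprotroph-Endophyte	Probable	Microfungus
Aspergillus	genus	Saprotroph	Undefined Saprotroph	Possible	Microfungus
Acremonium	genus	Saprotroph-Symbiotroph	Undefined Saprotroph-Endophyte	Possible	Microfungus
Trichoderma	genus	Saprotroph	Fungicolous-Undefined Saprotroph	Possible	Microfungus
Nectriaceae	family	Pathotroph-Saprotroph-Symbiotroph	Plant Pathogen-Undefined Saprotroph-Endophyte	Probable	Microfungus
Pleosporaceae	family	Pathotroph-Saprotroph	Plant Pathogen-Undefined Saprotroph	Probable	Microfungus
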