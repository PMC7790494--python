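{
  "layers": [
    "L1", "L2", "L3", "L4", "L5", "L6", "L6b",
    "L1/2", "L2/3", "L3/4", "L4/5", "L5/6", "L2-5"
  ],
  "projections": ["IT", "ET", "CT", "NP"],
  "projection_aliases": {"CF": "ET", "PT": "ET"},
  "genes": [
    "Pvalb", "Sst", "Vip", "Sncg", "Lamp5", "Chodl", "Npy", "Ahr",
    "Meis2", "Gad1", "Gad2", "Pax6"
  ],
  "classes": [
    "Microglia", "Astrocyte", "Astro", "Oligodendrocyte", "Oligo", "OPC",
    "Endothelial", "Endo", "VLMC", "Pericyte", "Peri", "PVM", "SMC",
    "Glutamatergic", "GABAergic", "Non-neuronal", "Neuron"
  ],
  "historical": [
    "Chandelier", "Rosehip", "Martinotti", "Neurogliaform", "Basket",
    "Double bouquet", "Pyramidal", "Von Economo", "Betz"
  ]
}
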