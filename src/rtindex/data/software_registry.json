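[
  "ImageJ", "Fiji", "FIJI", "GraphPad Prism", "Prism", "MATLAB", "SPSS",
  "NEURON", "FlowJo", "CellProfiler", "Bioconductor", "RStudio", "Stata",
  "LabVIEW", "Photoshop", "Imaris", "MetaMorph", "SnapGene", "Geneious",
  "Cytoscape", "PyMOL", "ChimeraX", "Bowtie2", "Bowtie", "HISAT2",
  "DESeq2", "edgeR", "limma", "Seurat", "Scanpy", "Microsoft Excel",
  "Excel", "Python", "Ethovision", "EthoVision", "ZEN", "BLAST",
  "ClustalW", "MAFFT", "MEGA7", "MEGA X", "Minitab", "OriginPro",
  "Igor Pro", "pClamp", "Clampfit", "MiniAnalysis", "Kaluza", "CellQuest"
]
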