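"""Shared fixtures: golden example sentences and a session-wide engine."""

from __future__ import annotations

import pytest

from rtindex.detectors import PatternEngine

# Canonical example sentences for each rigor criterion, as printed in the
# published criterion taxonomy; the engine must label every one correctly.
RIGOR_GOLDEN: dict[str, list[str]] = {
    "IRB": [
        "All human work was conducted under human subjects protocols approved by "
        "the Stanford Institutional Review Board (IRB), the University of Michigan "
        "UM-IRBMED, and the ethical committee of d'Ile de France II.",
        "The trial was approved by the NRES committee London-South East.",
    ],
    "CONSENT": [
        "Written informed consent was obtained from parents of all participating "
        "children and oral assent was obtained from 7-year-olds.",
        "All infants were enrolled with informed parental permission under a "
        "protocol that was reviewed and approved by the Institutional Review "
        "Boards of the respective study sites.",
    ],
    "IACUC": [
        "All animal experiments were performed in accordance with relevant "
        "guidelines and regulations and were approved by the University of "
        "Pennsylvania Institutional Animal Care and Use Committee (IACUC).",
        "All animals used in this study were treated in accordance with UK animal "
        "(scientific procedures) legislation and under the appropriate project "
        "licenses, national and local ethical approval.",
    ],
    "RANDOMIZATION": [
        "Animals were assigned to experimental groups using simple randomization.",
        "Communication with schools, and elicitation of willingness to "
        "participate, was conducted before the village-level randomization took place.",
    ],
    "BLINDING": [
        "Responses were then scored by an experimenter blinded to injection "
        "condition and experimental cohort.",
        "All the analysis was performed by a person unaware of the experimental question.",
    ],
    "POWER": [
        "Sample size was based on estimations by power analysis with a level of "
        "significance of 0.05 and a power of 0.9.",
        "Sample size calculation was done for the primary aim of this study, "
        "i.e., FMD, as reported previously.",
    ],
    "SEX": [
        "Six healthy adult rhesus macaques (Macaca mulatta) of Chinese origin "
        "(4-8 kg, three males and three females, 4-8 years old) were inoculated "
        "intramuscularly (i.m.) with 1,000 pfu of EBOV Makona strain.",
        "In each session, the behavior of each mother was recorded every 2 min.",
    ],
    "CELL_AUTH": [
        "MOLM-14 cells were authenticated by STR profiling and flow cytometry.",
        "All cell lines were obtained from ATCC, tested negative for mycoplasma, "
        "and their identity was verified by short tandem repeat analysis "
        "(Promega GenePrint 10 system).",
    ],
    "CELL_CONTAM": [
        "All cell lines were obtained from ATCC and tested negative for "
        "mycoplasma contamination.",
        "All cell lines were confirmed to be mycoplasma free using a PCR-based "
        "detection strategy with positive and negative controls.",
    ],
}

RESOURCE_GOLDEN: dict[str, list[str]] = {
    "ANTIBODY": [
        "ATF3 antibody (Santa Cruz Biotechnology) was used at 1:2000.",
        "Slices were then washed (3x) and placed in PBS containing the following: "
        "1% (vol/vol) normal goat serum, 1% (vol/vol) BSA, 0.25% (vol/vol) Triton "
        "X-100, and mouse monoclonal anti-5.8S rRNA, clone Y10b at 1:500 "
        "(Abcam, ab37144, RRID: AB_777714) overnight at 4C.",
    ],
    "ORGANISM": [
        "Adult (10-12 weeks; 25-30g) male C57BL/6 and TH-Cre mice were "
        "group-housed until surgery.",
        "To generate the deletion the following sgRNA was generated "
        "5'-GCAGGAGGAGGTACAGCGGG-3' and cloned into pU6-2-BbsI-gRNA (DGRC #1363) "
        "and then subsequently injected into w1118; vas-Cas9 "
        "(RRID:BDSC_51324, rainbow transgenics).",
        "The transgenic lines used in this study were Tg(kdrl:EGFP)s843, "
        "Tg(lyve1b:dsRed2)nz101 and Tg(mpeg1:EGFP)gl22.",
    ],
    "CELL_LINE": [
        "The lung cancer cell line, H1299, was obtained from the American Tissue "
        "Culture Collection (Manassas, VA).",
        "J774A.1 murine monocytes and macrophages (ATCC, number TIB-67) were "
        "cultured at 37C in a humidified atmosphere in RPMI medium supplemented "
        "with 10% (v/v) heat-inactivated fetal bovine serum.",
    ],
    "PLASMID": [
        "The constructions were prepared using the vector pSpCas9(BB)-2A-Puro "
        "(PX459) V2.0, which was a gift from a colleague "
        "(Addgene plasmid #62988; RRID: Addgene_62988).",
        "For expression in HEK293 cells, INF2 was first subcloned into pGADT7.3 "
        "(BspEI/XmaI-XhoI) and then into pEGFP-C3 (EcoRI-SalI).",
    ],
    "OLIGO": [
        "Mutations were screened with one new oligonucleotide primer pair: "
        "Ex34B-f: 5'-GCCAGTACAACCCACTACGG-3'; Ex34B-r: 5'-CCTGAAGCACTGGAA-AGGAC-3'.",
        "Primers used were GRHL2-1-424-F (TATATAGGATCCATGTCACAAGAGTCGGACAA) and "
        "GRHL2-438-625-R (TTATATGTCGACCTAGATTTCCATGAGCGTGA).",
    ],
    "SOFTWARE": [
        "ImageJ was used to process and analyze raw images.",
        "All simulations were performed using the NEURON simulation environment.",
    ],
}

DISTRACTORS = [
    "The cells were washed in buffer.",
    "The blind-ended duct was ligated and examined under a dissection microscope.",
    "Expression of the maleless gene was quantified by qPCR.",
    "The laser power was set to 10 mW for all imaging sessions.",
    "Protein concentration was determined by BCA assay.",
]


@pytest.fixture(scope="session")
def engine() -> PatternEngine:
    return PatternEngine()
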