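"""Synthetic methods-section corpus with known ground truth.

Documents are assembled from slot-filled template sentences: one template
pool per rigor criterion, one per resource type (with and without
identifying metadata), plus a distractor pool that includes hard negatives
(e.g. "blind-ended duct", the *maleless* gene) to exercise the exclusion
lexicons.  Criterion prevalences and identifiability probabilities default
to rates representative of the recent open-access biomedical literature
(see docs/methods.md) and are fully configurable.  Same spec + seed →
byte-identical corpus and ground truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from lxml import etree

from .corpus_io import read_plaintext
from .types import (
    Criterion,
    CriterionHit,
    Document,
    ResourceMention,
    ResourceType,
)

DEFAULT_JOURNALS: tuple[tuple[str, str], ...] = (
    ("Journal of Synthetic Neuroscience", "2000-0001"),
    ("Annals of Model Biology", "2000-0002"),
    ("Synthetic Cell Reports", "2000-0003"),
    ("Archives of Reproducible Research", "2000-0004"),
    ("Methods in Simulated Medicine", "2000-0005"),
    ("Open Benchwork", "2000-0006"),
)

#: Criterion prevalences representative of the recent literature: sex and
#: randomization are reported in roughly a third of papers, blinding and
#: power analysis in under a tenth, IACUC statements in about a quarter.
DEFAULT_CRITERION_PREVALENCE: dict[Criterion, float] = {
    Criterion.IRB: 0.30,
    Criterion.CONSENT: 0.25,
    Criterion.IACUC: 0.25,
    Criterion.RANDOMIZATION: 0.301,
    Criterion.BLINDING: 0.086,
    Criterion.POWER: 0.099,
    Criterion.SEX: 0.370,
    Criterion.CELL_AUTH: 0.10,
    Criterion.CELL_CONTAM: 0.12,
}

#: mean mentions per document and probability each is identifiable
DEFAULT_RESOURCE_CONFIG: dict[ResourceType, dict[str, float]] = {
    ResourceType.ANTIBODY: {"mean_mentions": 2.0, "identifiable_prob": 0.433},
    ResourceType.ORGANISM: {"mean_mentions": 1.0, "identifiable_prob": 0.22},
    ResourceType.CELL_LINE: {"mean_mentions": 2.0, "identifiable_prob": 0.393},
    ResourceType.SOFTWARE: {"mean_mentions": 2.0, "identifiable_prob": 0.867},
    ResourceType.PLASMID: {"mean_mentions": 0.3, "identifiable_prob": 0.5},
    ResourceType.OLIGO: {"mean_mentions": 0.3, "identifiable_prob": 1.0},
}


@dataclass
class SyntheticCorpusSpec:
    n_docs: int
    journals: Sequence[tuple[str, str]] = DEFAULT_JOURNALS
    year_range: tuple[int, int] = (2015, 2019)
    criterion_prevalence: Mapping[Criterion, float] = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_PREVALENCE)
    )
    resource_config: Mapping[ResourceType, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RESOURCE_CONFIG.items()}
    )
    distractor_sentences: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not self.journals:
            raise ValueError("journal list must not be empty")
        for c, p in self.criterion_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {c} outside [0,1]: {p}")
        for t, cfg in self.resource_config.items():
            if cfg.get("mean_mentions", 0) < 0:
                raise ValueError(f"negative mean_mentions for {t}")
            if not 0.0 <= cfg.get("identifiable_prob", 0.0) <= 1.0:
                raise ValueError(f"identifiable_prob for {t} outside [0,1]")


# ---------------------------------------------------------------------------
# template pools (each template renders to exactly one segmentable sentence)
# ---------------------------------------------------------------------------

_UNIVERSITIES = (
    "Stanford University", "the University of Michigan", "the University of Toronto",
    "the Karolinska Institute", "the University of Pennsylvania",
)

CRITERION_TEMPLATES: dict[Criterion, tuple[str, ...]] = {
    Criterion.IRB: (
        "All human work was conducted under protocols approved by the {univ} Institutional Review Board.",
        "The study protocol was approved by the local ethics committee.",
        "This study received ethics approval from {univ}.",
    ),
    Criterion.CONSENT: (
        "Written informed consent was obtained from all participants.",
        "All subjects provided informed consent prior to enrollment.",
        "Infants were enrolled with informed parental permission.",
    ),
    Criterion.IACUC: (
        "All animal experiments were approved by the {univ} Institutional Animal Care and Use Committee (IACUC).",
        "Animal procedures were carried out under the appropriate project licenses.",
        "Housing and handling followed protocols reviewed by the institutional animal care and use committee.",
    ),
    Criterion.RANDOMIZATION: (
        "Animals were assigned to experimental groups using simple randomization.",
        "Subjects were randomly assigned to treatment groups.",
        "Processing order was randomized across batches.",
    ),
    Criterion.BLINDING: (
        "Responses were scored by an experimenter blinded to the experimental condition.",
        "All analysis was performed by a person unaware of the experimental question.",
        "Outcome assessment was carried out by a blinded observer.",
    ),
    Criterion.POWER: (
        "Sample size was based on estimations by power analysis with a significance level of 0.05 and a power of 0.9.",
        "A sample-size calculation indicated that {n} subjects per group were required.",
        "Group sizes were chosen to achieve a statistical power of 0.8.",
    ),
    Criterion.SEX: (
        "Participants included {a} males and {b} females aged 20 to 35 years.",
        "Both male and female subjects were included in all experiments.",
        "The sex of each subject was recorded at enrollment.",
    ),
    Criterion.CELL_AUTH: (
        "All cell lines were authenticated by STR profiling prior to use.",
        "Cell line identity was verified by short tandem repeat analysis.",
    ),
    Criterion.CELL_CONTAM: (
        "All cell lines tested negative for mycoplasma contamination.",
        "Cultures were confirmed to be mycoplasma free by PCR.",
    ),
}

# Distractors are criterion- and resource-free, with hard negatives for the
# sex and blinding exclusion rules.
DISTRACTOR_POOL: tuple[str, ...] = (
    "The blind-ended duct was ligated and examined under a dissection microscope.",
    "Expression of the maleless gene was quantified by qPCR.",
    "Sections were washed three times in PBS and mounted on glass slides.",
    "The laser power was set to 10 mW for all imaging sessions.",
    "Protein concentration was determined by BCA assay.",
    "Supernatants were collected and stored at -80°C until analysis.",
    "Tissue sections were stained with hematoxylin and eosin.",
    "The reaction was incubated at 37°C for 2 h.",
    "Membranes were blocked in 5% nonfat milk for 1 h at room temperature.",
    "Images were acquired on a confocal microscope at 63x magnification.",
)

_ANTIBODY_TARGETS = (
    "ATF3", "GFAP", "NeuN", "COX2", "TH", "Iba1", "PSD-95", "synaptophysin",
    "vimentin", "E-cadherin",
)
_ANTIBODY_VENDOR_CATALOGS = (
    ("Abcam", "ab{num5}"),
    ("Santa Cruz Biotechnology", "sc-{num4}"),
    ("Cell Signaling Technology", "#{num4}"),
    ("Sigma-Aldrich", "cat. no. A{num4}"),
)
_ANTIBODY_VENDORS_ONLY = (
    "Santa Cruz Biotechnology", "Abcam", "Millipore", "BioLegend",
)

_ORGANISMS = (
    ("C57BL/6J mice", "C57BL/6J", "IMSR_JAX:{num6}"),
    ("BALB/cJ mice", "BALB/cJ", "IMSR_JAX:{num6}"),
    ("Wistar rats", "Wistar", "RGD_{num6}"),
    ("Sprague-Dawley rats", "Sprague-Dawley", "RGD_{num6}"),
    ("zebrafish", "zebrafish", "ZFIN_ZDB-GENO-{num6}"),
    ("Drosophila", "Drosophila", "BDSC_{num5}"),
)

_CELL_LINES = ("HeLa", "HEK293", "A549", "U2OS", "Jurkat", "HepG2", "MCF-7", "K562")
_CELL_CATALOGS = ("CCL-{num3}", "CRL-{num4}", "TIB-{num2}")

_SOFTWARE_KNOWN = ("ImageJ", "GraphPad Prism", "MATLAB", "FlowJo", "CellProfiler", "Fiji")
_SOFTWARE_UNKNOWN = (
    "MorphoTrack", "SpikeSorterX", "QuantiPro", "CellCountr", "TraceViewer", "NeuroBatch",
)

_PLASMIDS = ("pEGFP-C3", "pGADT7", "pLKO.1", "pX459", "pUC19")


def _num(rng: np.random.Generator, digits: int) -> str:
    return "".join(str(rng.integers(0, 10)) for _ in range(digits))


def _fill_nums(template: str, rng: np.random.Generator) -> str:
    out = template
    for d in (6, 5, 4, 3, 2):
        while f"{{num{d}}}" in out:
            out = out.replace(f"{{num{d}}}", _num(rng, d), 1)
    return out


def _render_criterion(criterion: Criterion, rng: np.random.Generator) -> str:
    tpl = CRITERION_TEMPLATES[criterion][rng.integers(0, len(CRITERION_TEMPLATES[criterion]))]
    return tpl.format(
        univ=_UNIVERSITIES[rng.integers(0, len(_UNIVERSITIES))],
        n=int(rng.integers(8, 25)),
        a=int(rng.integers(3, 20)),
        b=int(rng.integers(3, 20)),
    )


def _render_resource(
    rtype: ResourceType, name_idx: int, identifiable: bool, rng: np.random.Generator
) -> tuple[str, str]:
    """Render one resource sentence; returns (sentence, ground-truth name)."""
    if rtype is ResourceType.ANTIBODY:
        # sentence-initial position requires a capital for clean segmentation
        target = _ANTIBODY_TARGETS[name_idx]
        target = target[0].upper() + target[1:]
        dil = int(rng.integers(2, 20)) * 100
        if identifiable:
            vendor, cat_tpl = _ANTIBODY_VENDOR_CATALOGS[
                rng.integers(0, len(_ANTIBODY_VENDOR_CATALOGS))
            ]
            cat = _fill_nums(cat_tpl, rng)
            extra = f", RRID: AB_{_num(rng, 6)}" if rng.random() < 0.5 else ""
            return (
                f"{target} antibody ({vendor}, {cat}{extra}) was used at 1:{dil}.",
                f"{target} antibody",
            )
        vendor = _ANTIBODY_VENDORS_ONLY[rng.integers(0, len(_ANTIBODY_VENDORS_ONLY))]
        return (
            f"{target} antibody ({vendor}) was diluted in blocking buffer.",
            f"{target} antibody",
        )

    if rtype is ResourceType.ORGANISM:
        phrase, name, rrid_tpl = _ORGANISMS[name_idx]
        if identifiable:
            rrid = _fill_nums(rrid_tpl, rng)
            return (
                f"{phrase.capitalize() if phrase[0].islower() else phrase} "
                f"(RRID:{rrid}) were obtained for this study.",
                name,
            )
        return (f"{phrase[0].upper()}{phrase[1:]} were housed under a 12 h light cycle.", name)

    if rtype is ResourceType.CELL_LINE:
        cell = _CELL_LINES[name_idx]
        if identifiable:
            if rng.random() < 0.5:
                cat = _fill_nums(_CELL_CATALOGS[rng.integers(0, len(_CELL_CATALOGS))], rng)
                return (f"{cell} cells were obtained from ATCC (cat. no. {cat}).", cell)
            return (f"{cell} cells (RRID:CVCL_{_num(rng, 4)}) were used for all assays.", cell)
        return (f"{cell} cells were cultured in DMEM supplemented with 10% FBS.", cell)

    if rtype is ResourceType.SOFTWARE:
        if identifiable:
            tool = _SOFTWARE_KNOWN[name_idx]
            return (f"Images and data were analyzed using {tool}.", tool)
        tool = _SOFTWARE_UNKNOWN[name_idx]
        return (f"Signals were processed with {tool} software.", tool)

    if rtype is ResourceType.PLASMID:
        plasmid = _PLASMIDS[name_idx]
        if identifiable:
            num = _num(rng, 5)
            return (
                f"The construct was cloned into the vector {plasmid} "
                f"(Addgene plasmid #{num}; RRID: Addgene_{num}).",
                plasmid,
            )
        return (f"The coding sequence was subcloned into {plasmid}.", plasmid)

    if rtype is ResourceType.OLIGO:
        seq = "".join("ACGT"[rng.integers(0, 4)] for _ in range(18))
        return (f"Primers ({seq}) were used for qPCR amplification.", seq)

    raise ValueError(f"unknown resource type {rtype}")


def _software_pool_size(identifiable: bool) -> int:
    return len(_SOFTWARE_KNOWN) if identifiable else len(_SOFTWARE_UNKNOWN)


_POOL_SIZES = {
    ResourceType.ANTIBODY: len(_ANTIBODY_TARGETS),
    ResourceType.ORGANISM: len(_ORGANISMS),
    ResourceType.CELL_LINE: len(_CELL_LINES),
    ResourceType.SOFTWARE: len(_SOFTWARE_KNOWN),  # per identifiability class
    ResourceType.PLASMID: len(_PLASMIDS),
    ResourceType.OLIGO: 10_000,
}


def generate_corpus(spec: SyntheticCorpusSpec) -> tuple[list[Document], dict]:
    """Generate documents and their ground truth.

    Ground truth maps ``doc_id`` to the planted criterion sentence indices
    and resource mentions (with identifiability).  Deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    documents: list[Document] = []
    ground_truth: dict[str, dict] = {}

    journals = list(spec.journals)
    y_lo, y_hi = spec.year_range

    for i in range(spec.n_docs):
        doc_id = f"SYN{i:05d}"
        journal, issn = journals[rng.integers(0, len(journals))]
        year = int(rng.integers(y_lo, y_hi + 1))

        planned: list[tuple[str, object, str]] = []  # (kind, payload, sentence)

        for criterion in Criterion:
            p = spec.criterion_prevalence.get(criterion, 0.0)
            if rng.random() < p:
                planned.append(("criterion", criterion, _render_criterion(criterion, rng)))

        for rtype in ResourceType:
            cfg = spec.resource_config.get(rtype)
            if not cfg:
                continue
            k = int(rng.poisson(cfg.get("mean_mentions", 0.0)))
            if k == 0:
                continue
            if rtype is ResourceType.SOFTWARE:
                # identifiable and non-identifiable tools come from disjoint
                # name pools, sampled without replacement within a document
                flags = [bool(rng.random() < cfg["identifiable_prob"]) for _ in range(k)]
                idx_known = [int(x) for x in rng.permutation(len(_SOFTWARE_KNOWN))]
                idx_unknown = [int(x) for x in rng.permutation(len(_SOFTWARE_UNKNOWN))]
                for flag in flags:
                    pool = idx_known if flag else idx_unknown
                    if not pool:
                        continue
                    sentence, name = _render_resource(rtype, pool.pop(), flag, rng)
                    planned.append(("mention", (rtype, name, flag), sentence))
            else:
                k = min(k, _POOL_SIZES[rtype])
                name_indices = rng.permutation(_POOL_SIZES[rtype])[:k] if rtype is not ResourceType.OLIGO else range(k)
                for name_idx in name_indices:
                    flag = bool(rng.random() < cfg["identifiable_prob"])
                    sentence, name = _render_resource(rtype, int(name_idx), flag, rng)
                    planned.append(("mention", (rtype, name, flag), sentence))

        for _ in range(spec.distractor_sentences):
            planned.append(
                ("distractor", None, DISTRACTOR_POOL[rng.integers(0, len(DISTRACTOR_POOL))])
            )

        order = rng.permutation(len(planned))
        sentences = [planned[j][2] for j in order]
        methods_text = " ".join(sentences)

        truth_criteria: dict[str, list[int]] = {}
        truth_mentions: list[dict] = []
        for new_idx, j in enumerate(order):
            kind, payload, _sentence = planned[j]
            if kind == "criterion":
                truth_criteria.setdefault(payload.value, []).append(new_idx)
            elif kind == "mention":
                rtype, name, flag = payload
                truth_mentions.append(
                    {
                        "resource_type": rtype.value,
                        "name": name,
                        "sentence_index": new_idx,
                        "identifiable": flag,
                    }
                )

        doc = read_plaintext(methods_text, doc_id, journal, issn, year)
        if len(doc.sentences) != len(sentences):
            raise AssertionError(
                f"{doc_id}: segmentation produced {len(doc.sentences)} sentences "
                f"for {len(sentences)} templates"
            )
        documents.append(doc)
        ground_truth[doc_id] = {
            "journal": journal,
            "issn": issn,
            "year": year,
            "criteria": truth_criteria,
            "mentions": truth_mentions,
        }

    return documents, ground_truth


# ---------------------------------------------------------------------------
# detector evaluation
# ---------------------------------------------------------------------------

def evaluate_detectors(
    documents: Sequence[Document],
    ground_truth: Mapping[str, dict],
    hits_by_doc: Mapping[str, Sequence[CriterionHit]],
    mentions_by_doc: Mapping[str, Sequence[ResourceMention]],
) -> dict[str, dict[str, float]]:
    """Per-label precision/recall/F1, exact match on (doc, sentence, label)."""
    known_docs = {d.doc_id for d in documents}
    unknown = set(ground_truth) - known_docs
    if unknown:
        raise ValueError(f"ground truth references unknown documents: {sorted(unknown)}")

    truth: set[tuple[str, int, str]] = set()
    for doc_id, entry in ground_truth.items():
        for label, indices in entry.get("criteria", {}).items():
            for idx in indices:
                truth.add((doc_id, idx, label))
        for m in entry.get("mentions", []):
            truth.add((doc_id, m["sentence_index"], m["resource_type"]))

    predicted: set[tuple[str, int, str]] = set()
    for doc_id, hits in hits_by_doc.items():
        for h in hits:
            predicted.add((doc_id, h.sentence_index, h.criterion.value))
    for doc_id, mentions in mentions_by_doc.items():
        for m in mentions:
            predicted.add((doc_id, m.sentence_index, m.resource_type.value))

    labels = sorted({t[2] for t in truth} | {p[2] for p in predicted})
    report: dict[str, dict[str, float]] = {}
    for label in labels:
        t = {x for x in truth if x[2] == label}
        p = {x for x in predicted if x[2] == label}
        tp = len(t & p)
        precision = tp / len(p) if p else 0.0
        recall = tp / len(t) if t else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        report[label] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": float(len(t)),
        }
    return report


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def document_to_jats(document: Document) -> bytes:
    """Minimal JATS rendering of a synthetic document (round-trips through
    :func:`rtindex.corpus_io.read_jats`)."""
    article = etree.Element("article")
    front = etree.SubElement(article, "front")
    jm = etree.SubElement(front, "journal-meta")
    etree.SubElement(jm, "journal-title").text = document.journal
    etree.SubElement(jm, "issn").text = document.issn
    am = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(am, "article-id", attrib={"pub-id-type": "pmc"})
    aid.text = document.doc_id
    pd_el = etree.SubElement(am, "pub-date")
    etree.SubElement(pd_el, "year").text = str(document.year)
    body = etree.SubElement(article, "body")
    sec = etree.SubElement(body, "sec", attrib={"sec-type": "methods"})
    etree.SubElement(sec, "title").text = "Methods"
    etree.SubElement(sec, "p").text = document.methods_text
    return etree.tostring(article, xml_declaration=True, encoding="UTF-8")


def write_corpus(
    documents: Sequence[Document],
    ground_truth: Mapping[str, dict],
    outdir: str | Path,
    fmt: str = "jats",
) -> None:
    """Write one file per document plus ground_truth.json and manifest.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for doc in documents:
        if fmt == "jats":
            (outdir / f"{doc.doc_id}.xml").write_bytes(document_to_jats(doc))
        elif fmt == "text":
            (outdir / f"{doc.doc_id}.txt").write_text(doc.methods_text, encoding="utf-8")
            (outdir / f"{doc.doc_id}.json").write_text(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "journal": doc.journal,
                        "issn": doc.issn,
                        "year": doc.year,
                    }
                ),
                encoding="utf-8",
            )
        else:
            raise ValueError(f"unknown corpus format: {fmt!r}")
    (outdir / "ground_truth.json").write_text(
        json.dumps(dict(ground_truth), indent=1), encoding="utf-8"
    )
    with (outdir / "manifest.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_id", "journal", "issn", "year"])
        for doc in documents:
            writer.writerow([doc.doc_id, doc.journal, doc.issn, doc.year])
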