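"""Synthetic offline fixtures: mini-ontology, mini-lexicon, toy tool
repository, clinical questions and gold standards.

Everything here is synthetic stand-in data.  The mini-ontology emulates
the structure of the EDAM ontology (Data / Format / Operation / Topic /
Identifier roots) at 40 terms; the lexicon is a small UMLS-style
dictionary; the repository plants tools engineered backwards from target
score decompositions: each planted case carries literal query-term
occurrences in its input / output / description fields so that, against
the two bundled clinical questions, it receives exactly its intended
(in, out, tag) appearance counts.  Generation is deterministic: the same
seed yields byte-identical files, and a built-in verification step runs
the real recognizer + scorer over the generated files and fails loudly if
any planted case drifts from its intended counts.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

#: The two case-study clinical questions driving the planted fixtures.
QUESTION_1 = ("John has lung cancer and has been treated with carboplatin "
              "which is known for toxicology adverse effects. I would like "
              "to find literature and reference related to such events for "
              "the specific drug.")
QUESTION_2 = ("I have the miRNA gene expression profile of Anna which is a "
              "nephroblastoma patient. I want to identify KEGG pathways "
              "which are mainly disrupted due to gene expression.")


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedCase:
    tool_name: str
    question: str                 # "q1" | "q2"
    in_count: int
    out_count: int
    tag_count: int
    expected_score: float


@dataclass
class FixtureSpec:
    seed: int = 0
    n_tools: int = 30
    n_ontology_terms: int = 40
    planted_cases: tuple[PlantedCase, ...] = (
        PlantedCase("OncoStat API", "q1", 3, 1, 3, 4.75),
        PlantedCase("TumorAtlas API", "q1", 3, 0, 3, 3.75),
        PlantedCase("PharmLex API", "q1", 0, 1, 5, 2.25),
        PlantedCase("ThresholdCase API", "q1", 1, 0, 0, 1.0),
        PlantedCase("OncoRegistry Exporter", "q1", 2, 0, 1, 2.25),
        PlantedCase("LitMiner API", "q1", 0, 2, 2, 2.5),
        PlantedCase("MicroRNA PathFinder", "q2", 1, 2, 0, 3.0),
        PlantedCase("ExpressionPath Mapper", "q2", 0, 2, 0, 2.0),
    )


# ---------------------------------------------------------------------------
# Mini-ontology: (name, parent name, synonyms, subsets, definition, comment)

_ROOTS = ["Data", "Format", "Operation", "Topic", "Identifier"]

_TERMS: list[tuple[str, str, list[str], list[str], str, str]] = [
    # Format branch
    ("Text format", "Format", [], [], "A textual serialization format.", ""),
    ("Sequence format", "Format", [], ["formats"],
     "A format for biological sequences.", ""),
    ("VCF", "Text format", ["Variant Call Format"], ["formats"],
     "Variant call file listing genomic variants.", ""),
    ("TSV", "Text format", ["Tabular format"], [],
     "Tab-separated values, a reproducible tabular layout.", ""),
    ("CSV", "Text format", [], [],
     "Comma-separated values, a reproducible tabular layout.", ""),
    ("XLS", "Format", ["Spreadsheet format"], [],
     "Spreadsheet workbook file.", ""),
    ("FASTA", "Sequence format", [], [],
     "Plain sequence records with header lines.", ""),
    ("SAM", "Sequence format", [], [],
     "Alignment records as tab-delimited text.", ""),
    ("BAM", "Sequence format", [], [],
     "Compressed alignment records.", "Binary companion of alignment text."),
    ("BED", "Text format", [], [], "Genomic interval lines.", ""),
    ("Newick", "Text format", [], [], "Parenthesized tree serialization.", ""),
    # Operation branch
    ("KEGG pathways", "Operation", ["KEGG pathway mapping"], [],
     "Assignment of molecular features to biochemical route diagrams.", ""),
    ("Sequence alignment", "Operation", [], [],
     "Arranging sequences to expose similarity.", ""),
    ("Variant calling", "Operation", [], [],
     "Detecting variants from aligned reads.", ""),
    ("Clustering", "Operation", [], [], "Grouping by similarity.", ""),
    ("Visualisation", "Operation", ["Plotting"], [],
     "Rendering results graphically.", ""),
    ("Annotation", "Operation", [], [],
     "Attaching descriptive metadata.", ""),
    ("Filtering", "Operation", [], [], "Removing unwanted records.", ""),
    ("Gene prediction", "Operation", [], [],
     "Locating coding regions.", ""),
    ("Indexing", "Operation", [], [], "Building lookup structures.", ""),
    # Data branch
    ("Matrix", "Data", [], [], "A rectangular numeric array.", ""),
    ("Sequence", "Data", [], [], "A biological sequence.", ""),
    ("Alignment", "Data", [], [], "Aligned sequence set.", ""),
    ("Expression matrix", "Matrix", [], [],
     "Abundance values per feature and sample.", ""),
    ("Pathway map", "Data", [], [], "A molecular interaction diagram.", ""),
    ("Phylogeny", "Data", [], [], "An evolutionary tree.", ""),
    ("Image", "Data", [], [], "A raster picture.", ""),
    # Topic branch
    ("Genomics", "Topic", [], [], "Study of genomes.", ""),
    ("Proteomics", "Topic", [], [], "Study of proteomes.", ""),
    ("Transcriptomics", "Topic", [], [], "Study of transcriptomes.", ""),
    ("Metabolomics", "Topic", [], [], "Study of metabolomes.", ""),
    ("Statistics", "Topic", [], [], "Statistical methodology.", ""),
    ("Oncology", "Topic", [], [], "Study of tumours.", ""),
    # Identifier branch
    ("Gene ID", "Identifier", [], [], "Accession of a gene record.", ""),
    ("Protein ID", "Identifier", [], [], "Accession of a protein record.", ""),
]


def make_mini_ontology(spec: FixtureSpec) -> str:
    """Render the mini-ontology as OBO 1.2 text (five roots + planted
    terms); deterministic for a given spec."""
    if spec.n_ontology_terms < 10:
        raise FixtureError("need at least 10 ontology terms")
    names = _ROOTS + [t[0] for t in _TERMS]
    if len(names) != spec.n_ontology_terms:
        raise FixtureError(
            f"term pool has {len(names)} names; spec demands "
            f"{spec.n_ontology_terms}")
    ids = {name: f"MINI:{i + 1:07d}" for i, name in enumerate(names)}

    lines = ["format-version: 1.2", "ontology: mini", ""]
    for name in _ROOTS:
        lines += [f"[Term]", f"id: {ids[name]}", f"name: {name}", ""]
    for name, parent, syns, subsets, definition, comment in _TERMS:
        lines += ["[Term]", f"id: {ids[name]}", f"name: {name}"]
        if definition:
            lines.append(f'def: "{definition}" []')
        for s in syns:
            lines.append(f'synonym: "{s}" EXACT []')
        for s in subsets:
            lines.append(f"subset: {s}")
        if comment:
            lines.append(f"comment: {comment}")
        lines.append(f"is_a: {ids[parent]} ! {parent}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Mini-lexicon (UMLS-style surrogate): surface, id, preferred name, types.

_CORE_LEXICON = [
    ("lung cancer", "C0242379", "Lung Neoplasm", "Neoplastic Process"),
    ("cancer", "C0006826", "Malignant Neoplasm", "Neoplastic Process"),
    ("lung", "C0024109", "Lung", "Body Part Organ or Organ Component"),
    ("carboplatin", "C0007258", "Carboplatin",
     "Pharmacologic Substance|Organic Chemical"),
    ("adverse effects", "C0879626", "Adverse Effects", "Finding"),
    ("toxicology", "C0040541", "Toxicology",
     "Biomedical Occupation or Discipline"),
    ("drug", "C0013227", "Pharmaceutical Preparations",
     "Pharmacologic Substance"),
    ("literature", "C0023866", "Literature", "Intellectual Product"),
    ("mirna", "C1101610", "MicroRNAs", "Nucleotide Sequence"),
    ("nephroblastoma", "C0027708", "Wilms Tumor", "Neoplastic Process"),
    ("patient", "C0030705", "Patients", "Patient or Disabled Group"),
    ("gene expression", "C0017262", "Gene Expression", "Genetic Function"),
    ("kegg pathways", "C1622963", "KEGG Pathway Database",
     "Intellectual Product"),
    ("vcf", "C5197543", "Variant Call Format File", "Intellectual Product"),
]

_FILLER_LEXICON = [
    ("aspirin", "C0004057", "Aspirin", "Pharmacologic Substance"),
    ("insulin", "C0021641", "Insulin", "Pharmacologic Substance"),
    ("diabetes", "C0011849", "Diabetes Mellitus", "Disease or Syndrome"),
    ("leukemia", "C0023418", "Leukemia", "Neoplastic Process"),
    ("chemotherapy", "C0013216", "Chemotherapy",
     "Therapeutic or Preventive Procedure"),
    ("vincristine", "C0042679", "Vincristine", "Pharmacologic Substance"),
    ("doxorubicin", "C0013089", "Doxorubicin", "Pharmacologic Substance"),
    ("surgery", "C0038895", "Surgery",
     "Therapeutic or Preventive Procedure"),
    ("biopsy", "C0005558", "Biopsy", "Diagnostic Procedure"),
    ("kidney", "C0022646", "Kidney", "Body Part Organ or Organ Component"),
    ("liver", "C0023884", "Liver", "Body Part Organ or Organ Component"),
    ("heart", "C0018787", "Heart", "Body Part Organ or Organ Component"),
    ("brain", "C0006104", "Brain", "Body Part Organ or Organ Component"),
    ("fever", "C0015967", "Fever", "Sign or Symptom"),
    ("headache", "C0018681", "Headache", "Sign or Symptom"),
    ("nausea", "C0027497", "Nausea", "Sign or Symptom"),
    ("influenza virus", "C0021400", "Influenza Virus", "Virus"),
    ("hepatitis b virus", "C0019169", "Hepatitis B Virus", "Virus"),
    ("vitamin d", "C0042866", "Vitamin D", "Vitamin"),
    ("vitamin c", "C0003968", "Ascorbic Acid", "Vitamin"),
    ("blood test", "C0018941", "Hematologic Test", "Laboratory Procedure"),
    ("blood", "C0005767", "Blood", "Tissue"),
    ("bone marrow", "C0005953", "Bone Marrow", "Tissue"),
    ("lymphocyte", "C0024264", "Lymphocyte", "Cell"),
    ("erythrocyte", "C0014792", "Erythrocyte", "Cell"),
    ("metabolism", "C0025519", "Metabolism", "Organism Function"),
    ("digestion", "C0012238", "Digestion", "Organism Function"),
    ("brca1", "C0376571", "BRCA1 Gene", "Gene or Genome"),
    ("tp53", "C0079419", "TP53 Gene", "Gene or Genome"),
    ("blood pressure", "C0005823", "Blood Pressure", "Clinical Attribute"),
    ("body weight", "C0005910", "Body Weight", "Clinical Attribute"),
    ("infant", "C0021270", "Infant", "Age Group"),
    ("elderly", "C0001792", "Aged", "Age Group"),
    ("pacemaker", "C0030163", "Pacemaker", "Medical Device"),
    ("catheter", "C0085590", "Catheter", "Medical Device"),
    ("fracture", "C0016658", "Fracture", "Injury or Poisoning"),
    ("poisoning", "C0032343", "Poisoning", "Injury or Poisoning"),
    ("milk", "C0026131", "Milk", "Food"),
    ("coffee", "C0009237", "Coffee", "Food"),
    ("childhood", "C0231335", "Childhood", "Temporal Concept"),
    ("postoperative", "C0032790", "Postoperative Period",
     "Temporal Concept"),
    ("protein sequence", "C0002520", "Amino Acid Sequence",
     "Amino Acid Sequence"),
    ("stenosis", "C1261287", "Stenosis", "Anatomical Abnormality"),
    ("antibody", "C0003241", "Antibody", "Immunologic Factor"),
    ("enzyme assay", "C1285250", "Enzyme Assay", "Laboratory Procedure"),
    ("relapse", "C0035020", "Relapse", "Finding"),
]


def make_lexicon(spec: FixtureSpec) -> str:
    """Render the lexicon fixture as TSV text."""
    rows = ["surface\tconcept_id\tpreferred_name\tsemantic_types"]
    for surface, cid, name, types in _CORE_LEXICON + _FILLER_LEXICON:
        rows.append(f"{surface}\t{cid}\t{name}\t{types}")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Tool repository.  Planted tools carry literal query-term occurrences in
# the facet that must pay points; filler tools are semantically inert.

_PLANTED_TOOLS = [
    {"name": "OncoStat API",
     "summary": "Cancer registry statistics service.",
     "tags": ["carboplatin", "drug", "literature"],
     "link": "https://example.org/oncostat",
     "input_formats": ["lung cancer", "carboplatin", "adverse effects"],
     "output_formats": ["drug"],
     "category": "Cancer statistics"},
    {"name": "TumorAtlas API",
     "summary": "Tumor cohort atlas with cancer genomics profiles.",
     "tags": ["carboplatin", "lung cancer", "adverse effects"],
     "link": "https://example.org/tumoratlas",
     "input_formats": ["lung cancer", "carboplatin", "adverse effects"],
     "output_formats": ["XLS"],
     "category": "Cancer genomics"},
    {"name": "PharmLex API",
     "summary": "Drug information and literature lookup.",
     "tags": ["drug", "literature", "drug"],
     "link": "https://example.org/pharmlex",
     "input_formats": [],
     "output_formats": ["drug"],
     "category": "Pharmacology"},
    {"name": "ThresholdCase API",
     "summary": "Agent index service.",
     "tags": [],
     "link": "https://example.org/threshold",
     "input_formats": ["carboplatin"],
     "output_formats": [],
     "category": "Pharmacology"},
    {"name": "OncoRegistry Exporter",
     "summary": "Exports registry records on carboplatin treatment.",
     "tags": [],
     "link": "https://example.org/oncoregistry",
     "input_formats": ["lung cancer", "carboplatin"],
     "output_formats": ["TSV"],
     "category": "Cancer statistics"},
    {"name": "LitMiner API",
     "summary": "Mines drug literature.",
     "tags": [],
     "link": "https://example.org/litminer",
     "input_formats": ["TSV"],
     "output_formats": ["literature", "drug"],
     "category": "Text mining"},
    {"name": "MicroRNA PathFinder",
     "summary": "Finds disrupted metabolic routes from small RNA profiles.",
     "tags": [],
     "link": "https://example.org/pathfinder",
     "input_formats": ["miRNA"],
     "output_formats": ["gene expression", "kegg pathways"],
     "category": "Pathway analysis"},
    {"name": "ExpressionPath Mapper",
     "summary": "Projects expression profiles onto curated maps.",
     "tags": [],
     "link": "https://example.org/expressionpath",
     "input_formats": ["FASTA"],
     "output_formats": ["gene expression", "kegg pathways"],
     "category": "Pathway analysis"},
]

_FILLER_TOOLS = [
    ("SeqAlign Suite", "Aligns reads against an assembly.", ["FASTA"],
     ["SAM"]),
    ("VarScope", "Browses called variant sets interactively.", ["VCF"],
     ["BED"]),
    ("TreeCraft", "Builds phylogenies from multiple alignments.", ["FASTA"],
     ["Newick"]),
    ("ChromPaint", "Renders chromosome ideograms.", ["BED"], ["Image"]),
    ("ReadTrim", "Trims low-quality bases from reads.", ["FASTA"], ["FASTA"]),
    ("CovPlotter", "Plots depth of coverage.", ["BAM"], ["Image"]),
    ("MotifScan", "Scans promoters for binding motifs.", ["FASTA"], ["TSV"]),
    ("ClusterView", "Interactive browser for cancer genomics cohorts.",
     ["CSV"], ["Image"]),
    ("ProtFold", "Predicts secondary structure of proteins.", ["FASTA"],
     ["CSV"]),
    ("GlycoBase", "Catalogue of glycan structures.", [], ["CSV"]),
    ("SpectraMatch", "Matches spectra to reference libraries.", [], ["TSV"]),
    ("CellCounter", "Counts segmented cells in micrographs.", ["Image"],
     ["CSV"]),
    ("FlowGater", "Automated gating of cytometry events.", ["CSV"], ["CSV"]),
    ("DoseTable", "Tabulates drug dosing schedules.", [], ["XLS"]),
    ("TrialIndex", "Registry of interventional study records.", [], ["CSV"]),
    ("BiblioGraph", "Maps citation networks from literature corpora.", [],
     ["Image"]),
    ("PrimerForge", "Designs amplification primers.", ["FASTA"], ["TSV"]),
    ("EpiTrack", "Tracks incidence time series.", ["CSV"], ["Image"]),
    ("MassCalib", "Calibrates spectrometer drift.", [], ["CSV"]),
    ("OmicsMerge", "Joins feature tables across assays.", ["CSV"], ["CSV"]),
    ("AnnoLift", "Lifts interval annotations between assemblies.", ["BED"],
     ["BED"]),
    ("QCReporter", "Summarizes run quality metrics.", ["BAM"], ["XLS"]),
]


def make_tool_repo(spec: FixtureSpec) -> list[dict]:
    """The repository record list: planted tools first, then seed-shuffled
    semantically inert fillers up to ``n_tools``."""
    n_fillers = spec.n_tools - len(_PLANTED_TOOLS)
    if n_fillers < 0 or n_fillers > len(_FILLER_TOOLS):
        raise FixtureError(f"cannot build {spec.n_tools} tools from the "
                           f"available pools")
    rng = random.Random(spec.seed)
    fillers = list(_FILLER_TOOLS)
    rng.shuffle(fillers)
    records = [dict(t) for t in _PLANTED_TOOLS]
    for name, summary, fin, fout in fillers[:n_fillers]:
        records.append({"name": name, "summary": summary, "tags": [],
                        "link": f"https://example.org/{name.lower()}",
                        "input_formats": fin, "output_formats": fout,
                        "category": "General"})
    return records


_GOLD = {
    "q1": {"relevant": ["OncoStat API", "TumorAtlas API", "PharmLex API",
                        "OncoRegistry Exporter", "LitMiner API",
                        "BiblioGraph", "DoseTable", "TrialIndex"],
           "full_solvers": ["OncoStat API"]},
    "q2": {"relevant": ["MicroRNA PathFinder", "ExpressionPath Mapper",
                        "OmicsMerge"],
           "full_solvers": ["MicroRNA PathFinder"]},
}


def _verify_planted(outdir: Path, spec: FixtureSpec) -> None:
    """Run the real pipeline over the generated files and check each
    planted case receives its intended appearance counts."""
    from .concepts import (EdamRecognizer, LexiconRecognizer, annotate_text,
                           load_lexicon)
    from .discovery import build_query, score_tool
    from .ontology import TermIndex, load_obo
    from .patterns import categorize
    from .repository import load_repository
    from .textproc import analyze, partition_question

    index = TermIndex(load_obo(outdir / "mini.obo"))
    lex = LexiconRecognizer(load_lexicon(outdir / "lexicon.tsv"))
    edam = EdamRecognizer(index)
    repo = load_repository(outdir / "tools.json")
    repo.annotate_all(edam, lex)

    queries = {}
    for qid, text in (("q1", QUESTION_1), ("q2", QUESTION_2)):
        anns = categorize(annotate_text(text, edam, lex))
        part = partition_question(analyze(text))
        queries[qid] = build_query(part, anns)

    for case in spec.planted_cases:
        scored = score_tool(queries[case.question],
                            repo.annotations[case.tool_name])
        got = (scored.in_matches, scored.out_matches, scored.tag_matches)
        want = (case.in_count, case.out_count, case.tag_count)
        if got != want or abs(scored.score - case.expected_score) > 1e-9:
            raise FixtureError(
                f"planted case {case.tool_name!r} on {case.question}: "
                f"intended (in, out, tag) {want} score "
                f"{case.expected_score}, generated fixture yields {got} "
                f"score {scored.score}")


def write_fixtures(outdir: str | Path, spec: FixtureSpec | None = None,
                   verify: bool = True) -> FixtureSpec:
    """Write mini.obo, lexicon.tsv, tools.json, questions/ and gold/ into
    ``outdir``; byte-identical for identical specs."""
    spec = spec or FixtureSpec()
    outdir = Path(outdir)
    (outdir / "questions").mkdir(parents=True, exist_ok=True)
    (outdir / "gold").mkdir(parents=True, exist_ok=True)

    (outdir / "mini.obo").write_text(make_mini_ontology(spec))
    (outdir / "lexicon.tsv").write_text(make_lexicon(spec))
    (outdir / "tools.json").write_text(
        json.dumps(make_tool_repo(spec), indent=1) + "\n")
    (outdir / "questions" / "q1.txt").write_text(QUESTION_1 + "\n")
    (outdir / "questions" / "q2.txt").write_text(QUESTION_2 + "\n")
    for qid, gold in _GOLD.items():
        lines = ["tool_name\tfull_solver"]
        for name in gold["relevant"]:
            flag = "yes" if name in gold["full_solvers"] else "no"
            lines.append(f"{name}\t{flag}")
        (outdir / "gold" / f"{qid}.tsv").write_text("\n".join(lines) + "\n")

    if verify:
        _verify_planted(outdir, spec)
    return spec
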