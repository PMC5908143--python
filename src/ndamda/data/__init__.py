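"""Bundled fixtures: case-study evidence tables and the toy input files.

The five evidence tables transcribe the published top-50 prediction lists
for breast neoplasms, oesophageal neoplasms, lymphoma, prostate neoplasms
and hepatocellular carcinoma, with each candidate's literature-evidence
label (database tags, or "Unconfirmed").
"""

from __future__ import annotations

from importlib import resources

from ..io import EvidenceTable, read_evidence_table

__all__ = ["EVIDENCE_DISEASES", "evidence_path", "load_evidence_table", "load_evidence_tables"]

EVIDENCE_DISEASES = [
    "breast_neoplasms",
    "oesophageal_neoplasms",
    "lymphoma",
    "prostate_neoplasms",
    "hepatocellular_carcinoma",
]


def evidence_path(name: str):
    """Filesystem path of a bundled evidence table."""
    ref = resources.files(__package__) / f"{name}.tsv"
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled evidence table named {name!r}")
    return ref


def load_evidence_table(name: str) -> EvidenceTable:
    return read_evidence_table(evidence_path(name), disease_name=name)


def load_evidence_tables() -> dict[str, EvidenceTable]:
    return {name: load_evidence_table(name) for name in EVIDENCE_DISEASES}


def toy_path(filename: str):
    """Filesystem path of one of the shipped toy input files."""
    ref = resources.files(__package__) / "toy" / filename
    if not ref.is_file():
        raise FileNotFoundError(f"no toy file named {filename!r}")
    return ref
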