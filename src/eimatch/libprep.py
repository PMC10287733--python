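"""Molecule filtering and deduplication for spectral-library construction.

GC-MS only sees volatile, modest-mass, non-ionic molecules, so candidate
structure lists from heterogeneous sources (experimental libraries, bioactivity
databases, metabolome databases) are pruned by five rules before spectra are
predicted for them:

R1  molecular mass < 1000 Da
R2  only the 11 elements common in EI-amenable organics: H C O N P S Cl F Br I Si
R3  not an ionic compound
R4  Crippen logP within [-12, 24]
R5  deduplication — within each dataset, then strictly across datasets in
    priority order so every molecule appears once in the union.

Identity for R5 is the full 27-character InChIKey by default (robust to SMILES
representation differences); canonical-SMILES equality is available as an
alternative key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

__all__ = [
    "ELEMENT_WHITELIST",
    "MoleculeRecord",
    "FilterReport",
    "DescriptorError",
    "compute_descriptors",
    "apply_filters",
    "dedup_within",
    "dedup_across",
    "dedup_keys_within",
    "dedup_keys_across",
    "filter_dataset",
]

#: R2 whitelist — the 11 elements retained for EI-MS library building.
ELEMENT_WHITELIST = frozenset(
    {"H", "C", "O", "N", "P", "S", "Cl", "F", "Br", "I", "Si"}
)

MASS_LIMIT_DA = 1000.0
LOGP_RANGE = (-12.0, 24.0)


class DescriptorError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        super().__init__(f"{reason}: {smiles!r}")
        self.smiles = smiles


@dataclass
class MoleculeRecord:
    """A molecule plus the descriptors the library filters consult."""

    smiles: str
    canonical_key: str
    mol_mass: float
    elements: frozenset[str]
    is_ionic: bool
    logp: float
    dataset: str = ""


@dataclass
class FilterReport:
    record: MoleculeRecord
    failed_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def compute_descriptors(
    smiles: str, dataset: str = "", key: str = "inchikey"
) -> MoleculeRecord:
    """Parse a SMILES and populate every descriptor the filters need.

    ``mol_mass`` is the average molecular weight (the value listed by the
    source databases), not monoisotopic.  A molecule is flagged ionic when any
    atom carries a nonzero formal charge after sanitization — this covers both
    drawn salts like ``[Na+].[Cl-]`` and single-fragment ions; neutral
    multi-fragment records (e.g. hydrates) are not ionic.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DescriptorError(smiles)
    mol_h = Chem.AddHs(mol)
    elements = frozenset(atom.GetSymbol() for atom in mol_h.GetAtoms())
    is_ionic = any(atom.GetFormalCharge() != 0 for atom in mol.GetAtoms())
    if key == "inchikey":
        canonical_key = Chem.MolToInchiKey(mol)
    elif key == "smiles":
        canonical_key = Chem.MolToSmiles(mol)
    else:
        raise ValueError(f"unknown canonical key scheme {key!r}")
    return MoleculeRecord(
        smiles=smiles,
        canonical_key=canonical_key,
        mol_mass=Descriptors.MolWt(mol),
        elements=elements,
        is_ionic=is_ionic,
        logp=Crippen.MolLogP(mol),
        dataset=dataset,
    )


def apply_filters(record: MoleculeRecord) -> FilterReport:
    """Evaluate rules R1-R4 on a descriptor-bearing record.

    The rules are independent, so every violated rule is reported, not just
    the first.  R5 (deduplication) operates on collections and lives in
    :func:`dedup_within` / :func:`dedup_across`.
    """
    failed = []
    if record.mol_mass >= MASS_LIMIT_DA:
        failed.append("R1")
    if not record.elements <= ELEMENT_WHITELIST:
        failed.append("R2")
    if record.is_ionic:
        failed.append("R3")
    if not LOGP_RANGE[0] <= record.logp <= LOGP_RANGE[1]:
        failed.append("R4")
    return FilterReport(record=record, failed_rules=failed)


# --- deduplication (R5) ---------------------------------------------------


def dedup_keys_within(keys: list) -> list:
    """Keep the first occurrence of each key, preserving order."""
    seen: set = set()
    out = []
    for k in keys:
        if k not in seen:
            seen.add(k)
            out.append(k)
    return out


def dedup_keys_across(datasets: list[list]) -> list[list]:
    """Cross-dataset dedup: earlier datasets have priority.

    A key present in dataset *i* is removed from every dataset *j > i*, so the
    union of the outputs has unique keys.  Each input is assumed already
    deduplicated within itself.
    """
    claimed: set = set()
    out = []
    for keys in datasets:
        kept = [k for k in keys if k not in claimed]
        claimed.update(kept)
        out.append(kept)
    return out


def dedup_within(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """First occurrence per canonical key is retained; order is stable."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.canonical_key not in seen:
            seen.add(r.canonical_key)
            out.append(r)
    return out


def dedup_across(datasets: list[list[MoleculeRecord]]) -> list[list[MoleculeRecord]]:
    """Cross-dataset dedup on records; priority order = input order."""
    claimed: set[str] = set()
    out = []
    for records in datasets:
        kept = [r for r in records if r.canonical_key not in claimed]
        claimed.update(r.canonical_key for r in kept)
        out.append(kept)
    return out


def filter_dataset(
    smiles_list: list[str], dataset: str = "", key: str = "inchikey"
) -> tuple[list[MoleculeRecord], list[FilterReport]]:
    """Run descriptors + R1-R4 + within-dataset dedup over a SMILES list.

    Returns the surviving records and a report for every input (unparseable
    SMILES yield a report with rule tag ``parse``).
    """
    reports: list[FilterReport] = []
    passed: list[MoleculeRecord] = []
    for smi in smiles_list:
        try:
            rec = compute_descriptors(smi, dataset=dataset, key=key)
        except DescriptorError:
            dummy = MoleculeRecord(
                smiles=smi, canonical_key="", mol_mass=0.0,
                elements=frozenset(), is_ionic=False, logp=0.0, dataset=dataset,
            )
            reports.append(FilterReport(record=dummy, failed_rules=["parse"]))
            continue
        rep = apply_filters(rec)
        reports.append(rep)
        if rep.passed:
            passed.append(rec)
    return dedup_within(passed), reports


def write_report(reports: list[FilterReport], path) -> None:
    """Tab-separated exclusion/inclusion table mirroring the filter audit."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("smiles\tcanonical_key\tmol_mass\tlogp\tpassed\tfailed_rules\n")
        for rep in reports:
            r = rep.record
            fh.write(
                f"{r.smiles}\t{r.canonical_key}\t{r.mol_mass:.4f}\t{r.logp:.4f}"
                f"\t{int(rep.passed)}\t{','.join(rep.failed_rules)}\n"
            )
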