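"""Assay design: in-silico digestion, candidate filtering, m/z arithmetic
and construction/serialization of the targeted quantification panel.

The panel is a machine-readable table of monitored peptides: for each
endogenous peptide it records the heavy-labeled twin, light/heavy
precursor m/z and charge, quantifier product ions, scheduled retention
time and the spiked amount of labeled peptide.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .masses import (
    CANONICAL_RESIDUES,
    HEAVY_K_DELTA,
    HEAVY_R_DELTA,
    MODIFICATION_DELTAS,
    PROTON,
    RESIDUE_MASSES,
    WATER,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinEntry:
    """A protein sequence with its accession."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(
                f"non-canonical residues {sorted(bad)} in {self.accession!r}"
            )


@dataclass
class PeptideCandidate:
    """A tryptic peptide produced by in-silico digestion."""

    sequence: str
    parent_accession: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int
    monoisotopic_mass: float
    is_unique: bool | None = None
    rejection_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("start/end positions inconsistent with length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass(frozen=True)
class ModificationSpec:
    """One of the three supported modifications."""

    name: str
    mass_delta: float | None = None
    max_per_peptide: int = 3

    def __post_init__(self) -> None:
        if self.name not in MODIFICATION_DELTAS:
            raise ValueError(f"unknown modification {self.name!r}")
        expected = MODIFICATION_DELTAS[self.name]
        if self.mass_delta is None:
            object.__setattr__(self, "mass_delta", expected)
        elif abs(self.mass_delta - expected) > 1e-4:
            raise ValueError(
                f"mass_delta {self.mass_delta} does not match {self.name}"
            )


@dataclass(frozen=True)
class HeavyLabel:
    """Stable-isotope label on the C-terminal K or R of a peptide."""

    residue: str

    def __post_init__(self) -> None:
        if self.residue not in ("K", "R"):
            raise ValueError("heavy label applies only to K or R")

    @property
    def mass_delta(self) -> float:
        return HEAVY_K_DELTA if self.residue == "K" else HEAVY_R_DELTA


HEAVY_K = HeavyLabel("K")
HEAVY_R = HeavyLabel("R")


def heavy_label_for(peptide: str) -> HeavyLabel:
    """Heavy label matching a peptide's C-terminal residue."""
    cterm = peptide[-1]
    if cterm not in ("K", "R"):
        raise ValueError(f"peptide {peptide!r} does not end in K or R")
    return HEAVY_K if cterm == "K" else HEAVY_R


@dataclass(frozen=True)
class TransitionDefinition:
    """A monitored product ion: y/b fragment or the precursor itself."""

    ion_type: str  # 'y', 'b' or 'p'
    ordinal: int | None
    product_charge: int
    theoretical_mz: float = 0.0

    def __post_init__(self) -> None:
        if self.ion_type not in ("y", "b", "p"):
            raise ValueError(f"ion_type must be y, b or p, got {self.ion_type!r}")
        if self.ion_type != "p" and (self.ordinal is None or self.ordinal < 1):
            raise ValueError("fragment ions need a positive ordinal")
        if self.product_charge not in (1, 2):
            raise ValueError("product charge must be 1 or 2")

    @property
    def label(self) -> str:
        charge = "+" * self.product_charge
        if self.ion_type == "p":
            return f"p{charge}"
        return f"{self.ion_type}{self.ordinal}{charge}"


_ION_RE = re.compile(r"^([ybp])(\d*)(\++)$", re.IGNORECASE)


def parse_ion_label(label: str) -> TransitionDefinition:
    """Parse a product-ion token like ``y7+``, ``b12++`` or ``p+``.

    Neutral-loss suffixes are not generated by this package; a label
    carrying one is rejected.
    """
    m = _ION_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse ion label {label!r}")
    ion_type = m.group(1).lower()
    ordinal = int(m.group(2)) if m.group(2) else None
    if ion_type != "p" and ordinal is None:
        raise ValueError(f"fragment label {label!r} lacks an ordinal")
    return TransitionDefinition(ion_type, ordinal, len(m.group(3)))


@dataclass
class PanelRow:
    """One monitored peptide with its heavy twin and transitions."""

    protein_id: str
    peptide: str
    labeled_peptide: str
    light_mz: float
    heavy_mz: float
    charge: int
    transitions: list[TransitionDefinition]
    rt_min: float
    spike_fmol: float

    @property
    def heavy_label(self) -> HeavyLabel:
        return heavy_label_for(self.peptide)


#: Skyline-style transition-selection settings used to build the panel.
DEFAULT_PANEL_SETTINGS = {
    "precursor_charges": (2, 3),
    "ion_charges": (1, 2),
    "ion_types": ("y", "b", "p"),
    "ion_match_tolerance_da": 0.5,
    "product_ions_picked": 10,
}


@dataclass
class AssayPanel:
    """The full monitored-peptide panel plus its selection settings."""

    rows: list[PanelRow]
    settings: dict = field(default_factory=lambda: dict(DEFAULT_PANEL_SETTINGS))

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def peptides(self) -> list[str]:
        return [r.peptide for r in self.rows]

    @property
    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.protein_id, None)
        return list(seen)

    def row_for(self, peptide: str) -> PanelRow:
        for r in self.rows:
            if r.peptide == peptide:
                return r
        raise KeyError(f"peptide {peptide!r} not in panel")

    @property
    def n_precursors(self) -> int:
        """Scheduled precursors: one light plus one heavy per row."""
        return 2 * len(self.rows)


# ---------------------------------------------------------------------------
# Mass / m/z arithmetic
# ---------------------------------------------------------------------------


def compute_peptide_mass(
    sequence: str,
    modifications: Sequence[ModificationSpec] = (),
    heavy: HeavyLabel | None = None,
) -> float:
    """Monoisotopic neutral mass of a peptide in Da.

    Sum of residue masses plus water, plus any modification deltas,
    plus the heavy-label delta when ``heavy`` is given.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    try:
        mass = sum(RESIDUE_MASSES[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None
    mass += WATER
    mass += sum(mod.mass_delta for mod in modifications)
    if heavy is not None:
        if sequence[-1] != heavy.residue:
            raise ValueError(
                f"heavy {heavy.residue} label on peptide ending in {sequence[-1]!r}"
            )
        mass += heavy.mass_delta
    return mass


def compute_precursor_mz(monoisotopic_mass: float, charge: int) -> float:
    """Precursor m/z = (M + z·proton)/z, rounded to 4 decimals."""
    if charge <= 0:
        raise ValueError("charge must be positive")
    if monoisotopic_mass < 0:
        raise ValueError("mass must be non-negative")
    return round((monoisotopic_mass + charge * PROTON) / charge, 4)


def compute_fragment_mz(
    peptide: str,
    ion_type: str,
    ordinal: int,
    product_charge: int = 1,
    heavy: HeavyLabel | None = None,
) -> float:
    """Theoretical m/z of a y- or b-fragment ion.

    y ions carry the C-terminus (and therefore the heavy label, when
    present); b ions carry the N-terminus and are unshifted by the label.
    """
    if ion_type not in ("y", "b"):
        raise ValueError("ion_type must be 'y' or 'b'")
    if not 1 <= ordinal <= len(peptide) - 1:
        raise ValueError(
            f"ordinal {ordinal} out of range for peptide of length {len(peptide)}"
        )
    if product_charge not in (1, 2):
        raise ValueError("product charge must be 1 or 2")
    if ion_type == "y":
        residues = peptide[-ordinal:]
        mass = sum(RESIDUE_MASSES[aa] for aa in residues) + WATER
        if heavy is not None:
            if peptide[-1] != heavy.residue:
                raise ValueError("heavy label does not match C-terminal residue")
            mass += heavy.mass_delta
    else:
        residues = peptide[:ordinal]
        mass = sum(RESIDUE_MASSES[aa] for aa in residues)
    return round((mass + product_charge * PROTON) / product_charge, 4)


def transition_mz(peptide: str, t: TransitionDefinition, charge: int,
                  heavy: bool = False) -> float:
    """m/z of a panel transition; ``p`` resolves to the precursor."""
    label = heavy_label_for(peptide) if heavy else None
    if t.ion_type == "p":
        return compute_precursor_mz(compute_peptide_mass(peptide, heavy=label), charge)
    return compute_fragment_mz(peptide, t.ion_type, t.ordinal, t.product_charge, label)


# ---------------------------------------------------------------------------
# Digestion / filtering / uniqueness
# ---------------------------------------------------------------------------


def digest_protein(
    entry: ProteinEntry, missed_cleavages_allowed: int = 0
) -> list[PeptideCandidate]:
    """Tryptic in-silico digestion of one protein.

    Cleaves C-terminal of K/R except when the next residue is P.
    With 0 missed cleavages the peptides tile the sequence exactly;
    higher settings add all runs of up to n+1 consecutive fragments.
    """
    if missed_cleavages_allowed < 0:
        raise ValueError("missed_cleavages_allowed must be >= 0")
    seq = entry.sequence
    # 0-based cut positions (cut after index i)
    cuts = [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    fragments = [
        (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]
    out: list[PeptideCandidate] = []
    for mc in range(missed_cleavages_allowed + 1):
        for i in range(len(fragments) - mc):
            start = fragments[i][0]
            end = fragments[i + mc][1]
            pep = seq[start:end]
            out.append(
                PeptideCandidate(
                    sequence=pep,
                    parent_accession=entry.accession,
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                    monoisotopic_mass=compute_peptide_mass(pep),
                )
            )
    return out


# Selection criteria for quantifiable peptides: 7-25 residues, fully
# cleaved, and free of Met/Cys/His.
MIN_PEPTIDE_LENGTH = 7
MAX_PEPTIDE_LENGTH = 25
FORBIDDEN_RESIDUES = "MCH"


def filter_candidates(
    candidates: Iterable[PeptideCandidate],
    proteome: Sequence[ProteinEntry],
    il_equivalent: bool = False,
) -> tuple[list[PeptideCandidate], list[PeptideCandidate]]:
    """Partition candidates into (kept, rejected-with-reasons).

    Kept peptides are 7-25 residues long, have no missed cleavages,
    contain none of M/C/H, and occur in exactly one proteome entry.
    Every violated rule is recorded on the rejected candidate.
    """
    kept: list[PeptideCandidate] = []
    rejected: list[PeptideCandidate] = []
    for cand in candidates:
        reasons: list[str] = []
        n = len(cand.sequence)
        if n < MIN_PEPTIDE_LENGTH:
            reasons.append(f"length<{MIN_PEPTIDE_LENGTH}")
        if n > MAX_PEPTIDE_LENGTH:
            reasons.append(f"length>{MAX_PEPTIDE_LENGTH}")
        if cand.missed_cleavages > 0:
            reasons.append("missed-cleavage")
        for aa in FORBIDDEN_RESIDUES:
            if aa in cand.sequence:
                reasons.append(f"contains-{aa}")
        uniq = check_uniqueness(cand.sequence, proteome, il_equivalent=il_equivalent)
        cand.is_unique = uniq["unique"]
        if not uniq["unique"]:
            reasons.append("not-unique" if uniq["matches"] else "not-found")
        cand.rejection_reasons = reasons
        (kept if not reasons else rejected).append(cand)
    return kept, rejected


def check_uniqueness(
    peptide: str,
    proteome: Sequence[ProteinEntry],
    il_equivalent: bool = False,
) -> dict:
    """Exact-substring uniqueness screen against a proteome.

    Returns ``{"unique": bool, "matches": [accessions]}``; unique means
    the peptide occurs in exactly one entry.  With ``il_equivalent``
    isoleucine and leucine are treated as the same letter.
    """
    if len(peptide) < 1:
        raise ValueError("peptide must have at least one residue")
    needle = peptide.replace("I", "L") if il_equivalent else peptide
    matches = []
    for entry in proteome:
        hay = entry.sequence.replace("I", "L") if il_equivalent else entry.sequence
        if needle in hay:
            matches.append(entry.accession)
    return {"unique": len(matches) == 1, "matches": matches}


# ---------------------------------------------------------------------------
# Panel construction & IO
# ---------------------------------------------------------------------------


def _auto_pick_transitions(peptide: str, charge: int, n: int = 3) -> list[TransitionDefinition]:
    """Pick singly-charged y/b ions with m/z above the precursor, largest first."""
    precursor = compute_precursor_mz(compute_peptide_mass(peptide), charge)
    pool: list[tuple[float, TransitionDefinition]] = []
    for ion_type in ("y", "b"):
        for ordinal in range(1, len(peptide)):
            mz = compute_fragment_mz(peptide, ion_type, ordinal, 1)
            if mz > precursor:
                pool.append((mz, TransitionDefinition(ion_type, ordinal, 1)))
    pool.sort(key=lambda p: -p[0])
    return [t for _, t in pool[:n]]


def _labeled_sequence(peptide: str) -> str:
    label = heavy_label_for(peptide)
    return f"{peptide[:-1]}[Heavy {label.residue}]"


def build_assay_panel(
    targets: Sequence[ProteinEntry],
    proteome: Sequence[ProteinEntry],
    spike_amounts: dict[str, float],
    extra_peptides: Sequence[str] = (),
    scheduled_rts: dict[str, float] | None = None,
    precursor_charge: int = 2,
) -> AssayPanel:
    """Assemble a panel from target proteins plus optional extra peptides.

    Extra peptides (e.g. derived from a previous shotgun experiment) skip
    the strict residue filters but must still map to a target protein.
    Every peptide with a positive spike amount becomes one panel row with
    light and heavy precursor m/z computed from first principles.
    """
    for amount in spike_amounts.values():
        if amount <= 0:
            raise ValueError("spike amounts must be positive")
    scheduled_rts = scheduled_rts or {}
    selected: list[tuple[str, str]] = []  # (protein_id, peptide)
    for target in targets:
        kept, _ = filter_candidates(digest_protein(target, 0), proteome)
        for cand in kept:
            if cand.sequence.endswith(("K", "R")):
                selected.append((target.accession, cand.sequence))
    for pep in extra_peptides:
        parents = [t.accession for t in targets if pep in t.sequence]
        if not parents:
            raise ValueError(f"extra peptide {pep!r} not found in any target")
        selected.append((parents[0], pep))

    rows: list[PanelRow] = []
    for protein_id, pep in selected:
        if pep not in spike_amounts:
            continue
        label = heavy_label_for(pep)
        light_mass = compute_peptide_mass(pep)
        rows.append(
            PanelRow(
                protein_id=protein_id,
                peptide=pep,
                labeled_peptide=_labeled_sequence(pep),
                light_mz=compute_precursor_mz(light_mass, precursor_charge),
                heavy_mz=compute_precursor_mz(light_mass + label.mass_delta,
                                              precursor_charge),
                charge=precursor_charge,
                transitions=_auto_pick_transitions(pep, precursor_charge),
                rt_min=scheduled_rts.get(pep, 0.0),
                spike_fmol=spike_amounts[pep],
            )
        )
    return AssayPanel(rows=rows)


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA; accession is the first header token."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append(
            ProteinEntry(
                accession=rec.id,
                sequence=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    return entries


def load_panel(path: str | Path) -> AssayPanel:
    """Load a panel CSV (see :func:`save_panel` for the dialect)."""
    rows: list[PanelRow] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                PanelRow(
                    protein_id=rec["protein_id"],
                    peptide=rec["peptide"],
                    labeled_peptide=rec["labeled_peptide"],
                    light_mz=float(rec["light_mz"]),
                    heavy_mz=float(rec["heavy_mz"]),
                    charge=int(rec["charge"]),
                    transitions=[
                        parse_ion_label(tok)
                        for tok in rec["product_ions"].split(";")
                        if tok
                    ],
                    rt_min=float(rec["rt_min"]),
                    spike_fmol=float(rec["spike_fmol"]),
                )
            )
    return AssayPanel(rows=rows)


def save_panel(panel: AssayPanel, path: str | Path) -> None:
    """Write the panel CSV: one row per monitored peptide."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["protein_id", "peptide", "labeled_peptide", "light_mz", "heavy_mz",
             "charge", "product_ions", "rt_min", "spike_fmol"]
        )
        for r in panel.rows:
            writer.writerow(
                [r.protein_id, r.peptide, r.labeled_peptide,
                 f"{r.light_mz:.4f}", f"{r.heavy_mz:.4f}", r.charge,
                 ";".join(t.label for t in r.transitions),
                 r.rt_min, r.spike_fmol]
            )


def export_transition_list(panel: AssayPanel, path: str | Path) -> None:
    """Skyline-style transition list: one row per (precursor, product)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["protein", "peptide", "isotope", "precursor_mz",
             "precursor_charge", "fragment", "product_mz", "product_charge"]
        )
        for r in panel.rows:
            for isotope, mz in (("light", r.light_mz), ("heavy", r.heavy_mz)):
                for t in r.transitions:
                    pmz = (mz if t.ion_type == "p"
                           else transition_mz(r.peptide, t, r.charge,
                                              heavy=isotope == "heavy"))
                    writer.writerow(
                        [r.protein_id, r.peptide, isotope, f"{mz:.4f}",
                         r.charge, t.label, f"{pmz:.4f}", t.product_charge]
                    )


def load_reference_panel() -> AssayPanel:
    """The bundled 21-peptide / 11-protein quantification panel fixture."""
    with resources.as_file(
        resources.files("prmquantkit.data") / "table1_panel.csv"
    ) as p:
        return load_panel(p)
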