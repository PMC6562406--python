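"""Derivatized-histone peptide library: digestion, peptidoforms, masses, m/z.

The substrate model: histones are chemically d3-acetylated at the protein level
before trypsin digestion. Every lysine that is unmodified (or monomethylated)
in vivo acquires a d3-acetyl group, which blocks tryptic cleavage at lysines, so
the effective digestion is "Arg-C-like": cleavage strictly C-terminal of
arginine. Each peptide family (e.g. H3 9-17) then exists as a combinatorial set
of peptidoforms, one per assignment of modification states to its lysines, and
each peptidoform is targeted as a 2+ and 3+ precursor in a light (sample) and a
heavy (Arg-10 super-SILAC spike-in) channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import fasta as _fasta
from pyteomics import mass as _pymass

from .constants import (
    ARG10_DELTA,
    H3_MATURE,
    MOD_STATES,
    PROTON,
    WATER,
    mod_shift,
)

# States a derivatized lysine can present in the light channel. "unmod" and
# "me1" never survive derivatization: they appear as d3ac / d3ac_me1.
DEFAULT_K_STATES = ("d3ac", "d3ac_me1", "me2", "me3", "ac")

# Human-readable label per chemical state (the biology behind the chemistry).
_STATE_LABEL = {
    "d3ac": "un",
    "d3ac_me1": "me1",
    "me2": "me2",
    "me3": "me3",
    "ac": "ac",
    "unmod": "un",
    "me1": "me1",
}

_CHARGES = (2, 3)


@dataclass(frozen=True)
class ResidueMod:
    """Modification state of one residue, 1-based on the mature protein."""

    position: int
    state: str

    def __post_init__(self):
        if self.state not in MOD_STATES:
            raise ValueError(f"unknown state {self.state!r} at {self.position}")


@dataclass(frozen=True)
class Peptidoform:
    """One peptide span with an explicit state on every lysine."""

    sequence: str
    start: int
    end: int
    mods: tuple[ResidueMod, ...]
    family_id: str

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("span length does not match sequence")
        object.__setattr__(
            self, "mods", tuple(sorted(self.mods, key=lambda m: m.position))
        )

    @property
    def form_id(self) -> str:
        """Stable identifier, e.g. ``H3_9-17:K9me3_K14ac`` or ``H3_9-17:unmod``.

        Lysines carrying only the derivatization tag (biologically unmodified)
        are omitted; a form with no in-vivo modification is ``unmod``.
        """
        parts = [
            f"K{m.position}{_STATE_LABEL[m.state]}"
            for m in self.mods
            if _STATE_LABEL[m.state] != "un"
        ]
        label = "_".join(parts) if parts else "unmod"
        return f"{self.family_id}:{label}"

    @property
    def n_arg(self) -> int:
        return self.sequence.count("R")

    def state_at(self, position: int) -> str:
        for m in self.mods:
            if m.position == position:
                return m.state
        raise KeyError(position)


@dataclass(frozen=True)
class IonSpecies:
    """Peptidoform x charge x SILAC channel, with its theoretical m/z."""

    peptidoform: Peptidoform
    charge: int
    channel: str
    mz: float


def read_reference_fasta(path) -> str:
    """First sequence of a FASTA file, uppercased (reference substrate)."""
    with _fasta.read(str(path)) as reader:
        for _, seq in reader:
            return str(seq).upper()
    raise ValueError(f"no sequence found in {path}")


def derivatize_and_digest(
    reference_sequence: str = H3_MATURE, max_missed_cleavages: int = 0
) -> list[tuple[int, int]]:
    """Arg-C-like digestion: cleave strictly C-terminal of R.

    Derivatized/modified lysines are never cleaved. Returns 1-based inclusive
    spans; with m missed cleavages allowed, every concatenation of up to m+1
    adjacent fragments is included.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    seq = reference_sequence
    for i, aa in enumerate(seq):
        if aa not in _pymass.std_aa_mass or aa in "UO":
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
    # base fragments: split after every R
    frags: list[tuple[int, int]] = []
    start = 1
    for i, aa in enumerate(seq, start=1):
        if aa == "R":
            frags.append((start, i))
            start = i + 1
    if start <= len(seq):
        frags.append((start, len(seq)))
    spans = []
    for i in range(len(frags)):
        for j in range(i, min(i + max_missed_cleavages + 1, len(frags))):
            spans.append((frags[i][0], frags[j][1]))
    return sorted(spans)


def enumerate_peptidoforms(
    span: tuple[int, int],
    allowed_states_per_k: Mapping[int, Sequence[str]] | None = None,
    reference_sequence: str = H3_MATURE,
    family_id: str | None = None,
) -> list[Peptidoform]:
    """Cartesian product of lysine states over one peptide span.

    ``allowed_states_per_k`` maps 1-based lysine position to its candidate
    states; lysines not listed get :data:`DEFAULT_K_STATES`. Ordering is
    deterministic: positions ascending, states in the given order.
    """
    start, end = span
    subseq = reference_sequence[start - 1 : end]
    fam = family_id or f"H3_{start}-{end}"
    k_positions = [start + i for i, aa in enumerate(subseq) if aa == "K"]
    if allowed_states_per_k:
        for pos in allowed_states_per_k:
            if reference_sequence[pos - 1] != "K":
                raise ValueError(f"position {pos} is not a lysine")
    state_lists = [
        tuple((allowed_states_per_k or {}).get(pos, DEFAULT_K_STATES))
        for pos in k_positions
    ]
    forms = []
    for combo in product(*state_lists):
        mods = tuple(
            ResidueMod(pos, st) for pos, st in zip(k_positions, combo)
        )
        forms.append(Peptidoform(subseq, start, end, mods, fam))
    return forms


def monoisotopic_mass(form: Peptidoform, precision_mode: str = "full") -> float:
    """Neutral monoisotopic mass: residue sum + water + modification shifts."""
    try:
        residue_sum = sum(_pymass.std_aa_mass[aa] for aa in form.sequence)
    except KeyError as e:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown residue {e.args[0]!r}") from None
    shifts = sum(mod_shift(m.state, precision_mode) for m in form.mods)
    return residue_sum + WATER + shifts


def mz(form: Peptidoform, charge: int, channel: str = "light") -> float:
    """Precursor m/z; the heavy channel adds the Arg-10 delta per arginine."""
    if charge not in _CHARGES:
        raise ValueError(f"charge must be one of {_CHARGES}, got {charge}")
    if channel not in ("light", "heavy"):
        raise ValueError(f"unknown channel {channel!r}")
    m = monoisotopic_mass(form)
    if channel == "heavy":
        m += form.n_arg * ARG10_DELTA
    return (m + charge * PROTON) / charge


def ion_species(form: Peptidoform) -> list[IonSpecies]:
    """All targeted ions of one peptidoform (2+/3+ x light/heavy)."""
    return [
        IonSpecies(form, z, ch, mz(form, z, ch))
        for z in _CHARGES
        for ch in ("light", "heavy")
    ]


# Default library: the H3 peptide families covered by the workflow, with the
# lysines open to the full state set except K37 (not part of any reported mark;
# held at the derivatized-unmodified state).
DEFAULT_FAMILY_SPANS = ((3, 8), (9, 17), (18, 26), (27, 40), (73, 83))
DEFAULT_STATE_RESTRICTIONS: dict[int, tuple[str, ...]] = {37: ("d3ac",)}


@dataclass
class PeptideLibrary:
    """The peptidoform universe of one analysis, keyed by form id."""

    forms: dict[str, Peptidoform] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        spans: Iterable[tuple[int, int]] = DEFAULT_FAMILY_SPANS,
        reference_sequence: str = H3_MATURE,
        state_restrictions: Mapping[int, Sequence[str]] | None = None,
    ) -> "PeptideLibrary":
        restrictions = (
            DEFAULT_STATE_RESTRICTIONS
            if state_restrictions is None
            else dict(state_restrictions)
        )
        forms: dict[str, Peptidoform] = {}
        for span in spans:
            for f in enumerate_peptidoforms(
                span, restrictions, reference_sequence
            ):
                forms[f.form_id] = f
        return cls(forms)

    def __len__(self) -> int:
        return len(self.forms)

    def __getitem__(self, form_id: str) -> Peptidoform:
        return self.forms[form_id]

    def __iter__(self):
        return iter(self.forms.values())

    @property
    def families(self) -> list[str]:
        seen = dict.fromkeys(f.family_id for f in self.forms.values())
        return list(seen)

    def family_forms(self, family_id: str) -> list[Peptidoform]:
        return [f for f in self.forms.values() if f.family_id == family_id]

    def to_frame(self) -> pd.DataFrame:
        """Export: one row per form with per-charge light/heavy m/z."""
        rows = []
        for f in self.forms.values():
            row = {
                "family_id": f.family_id,
                "form_id": f.form_id,
                "span": f"{f.start}-{f.end}",
                "sequence": f.sequence,
                "k_states": ";".join(
                    f"K{m.position}={m.state}" for m in f.mods
                ),
                "mass": monoisotopic_mass(f),
            }
            for z in _CHARGES:
                row[f"mz_light_{z}"] = mz(f, z, "light")
                row[f"mz_heavy_{z}"] = mz(f, z, "heavy")
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")
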