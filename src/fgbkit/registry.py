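"""Combinatorial color-code registry.

A color code is the combination of a fluorescent-protein combo (one or two
of hmAG3, YFP, mChEY), a chimeric antigen array (CAAR) permutation of three
antibody-detectable surface tags (HA, cMyc, Thy1.1) displayed on a shared
EGFRt membrane anchor, and a unique DNA barcode carried by the same vector.
Six fluorescent combos times eight CAAR permutations give 48 codes, each
with a distinct 7-channel boolean signature (hmAG3, YFP, mChEY, HA, cMyc,
Thy1.1, EGFRt); EGFRt is positive on every code and serves as the
vector-bearing-cell pre-gate.

Numbering convention
--------------------
Codes 1-24 are cMyc+ and 25-48 cMyc-. Within each half, the six fluorescent
combos occupy consecutive blocks of four CAAR permutations, with the fully
antibody-binding permutation first in each block, so codes 1, 5, 9, 13, 17
and 21 are HA+cMyc+Thy1.1+ across the six combos. The true bench assignment
of code numbers to marker combinations is not published beyond those
anchors; this ordering is the canonical convention of this package and is
explicit in every exported table.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("hmAG3", "YFP", "mChEY", "HA", "cMyc", "Thy1.1", "EGFRt")
FLUOR_CHANNELS = ("hmAG3", "YFP", "mChEY")
CAAR_CHANNELS = ("HA", "cMyc", "Thy1.1")

NUCLEOTIDES = "ACGT"


class FluorCombo(enum.Enum):
    """The six fluorescent-protein combinations (single or double positive).

    Triple-positive and all-negative patterns are never used as labels.
    """

    HMAG3 = frozenset({"hmAG3"})
    YFP = frozenset({"YFP"})
    MCHEY = frozenset({"mChEY"})
    YFP_HMAG3 = frozenset({"YFP", "hmAG3"})
    HMAG3_MCHEY = frozenset({"hmAG3", "mChEY"})
    YFP_MCHEY = frozenset({"YFP", "mChEY"})

    @property
    def positives(self) -> frozenset[str]:
        return self.value


# canonical block order of the six combos (single positives first)
FLUOR_ORDER: tuple[FluorCombo, ...] = (
    FluorCombo.HMAG3,
    FluorCombo.YFP,
    FluorCombo.MCHEY,
    FluorCombo.YFP_HMAG3,
    FluorCombo.HMAG3_MCHEY,
    FluorCombo.YFP_MCHEY,
)

_COMBO_BY_POSITIVES = {combo.value: combo for combo in FLUOR_ORDER}


def fluor_combo_from_positives(positives: Iterable[str]) -> FluorCombo | None:
    """Map a set of bright fluorescent channels to a combo, or None if the
    pattern (empty or triple-positive) is not a valid label."""
    return _COMBO_BY_POSITIVES.get(frozenset(positives))


@dataclass(frozen=True)
class CaarPermutation:
    """One of the 8 antibody-binding permutations of the surface-tag array.

    ``ha``/``cmyc`` True means the antibody-binding HA/cMyc tag (False the
    non-binding X variant); ``thy`` True means dThy1.1 (False dThy1.2).
    """

    ha: bool
    cmyc: bool
    thy: bool

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.ha, self.cmyc, self.thy)

    @staticmethod
    def all_permutations() -> tuple["CaarPermutation", ...]:
        return tuple(
            CaarPermutation(bool(h), bool(c), bool(t))
            for h in (1, 0)
            for c in (1, 0)
            for t in (1, 0)
        )


# CAAR block order within each cMyc half: full-binding first, then by
# (ha, thy) descending, so the antibody-binding-rich permutations lead.
def _caar_block(cmyc: bool) -> tuple[CaarPermutation, ...]:
    return tuple(
        CaarPermutation(bool(h), cmyc, bool(t)) for h, t in ((1, 1), (1, 0), (0, 1), (0, 0))
    )


@dataclass(frozen=True)
class ColorCode:
    """A single label state: fluorescent combo + CAAR permutation + barcode."""

    bc_id: int
    fluor: FluorCombo
    caar: CaarPermutation
    dna_barcode: str
    dhfr: bool = True

    def signature(self) -> tuple[bool, ...]:
        return expected_signature(self)


def expected_signature(code: ColorCode) -> tuple[bool, ...]:
    """Expected 7-channel boolean marker vector of a code.

    Order is ``CHANNELS`` = (hmAG3, YFP, mChEY, HA, cMyc, Thy1.1, EGFRt).
    EGFRt, the shared membrane anchor, is positive for every code.
    """
    pos = code.fluor.positives
    return (
        "hmAG3" in pos,
        "YFP" in pos,
        "mChEY" in pos,
        code.caar.ha,
        code.caar.cmyc,
        code.caar.thy,
        True,
    )


class RegistryConfigError(ValueError):
    """Raised when registry construction parameters are unsatisfiable."""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _random_barcodes(
    n: int, length: int, min_distance: int, rng: np.random.Generator, max_tries: int = 2000
) -> list[str]:
    """Draw n random nucleotide barcodes with pairwise Hamming >= min_distance."""
    barcodes: list[str] = []
    tries = 0
    while len(barcodes) < n:
        tries += 1
        if tries > max_tries:
            raise RegistryConfigError(
                f"could not place {n} barcodes of length {length} at pairwise "
                f"Hamming distance >= {min_distance} within {max_tries} draws; "
                "increase barcode_length"
            )
        candidate = "".join(rng.choice(list(NUCLEOTIDES), size=length))
        if all(_hamming(candidate, b) >= min_distance for b in barcodes):
            barcodes.append(candidate)
    return barcodes


@dataclass
class CodeRegistry:
    """The ordered collection of 48 color codes and their marker signatures."""

    codes: list[ColorCode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {c.bc_id: c for c in self.codes}
        self._by_signature = {expected_signature(c): c for c in self.codes}
        self._by_barcode = {c.dna_barcode: c for c in self.codes}

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)

    def code(self, bc_id: int) -> ColorCode:
        return self._by_id[bc_id]

    @property
    def bc_ids(self) -> list[int]:
        return [c.bc_id for c in self.codes]

    @property
    def barcode_length(self) -> int:
        return len(self.codes[0].dna_barcode)

    def lookup_signature(self, signature: Sequence[bool]) -> ColorCode | None:
        """Exact-match lookup of a 7-channel boolean vector; None if no code
        carries that signature (e.g. invalid fluorescent pattern)."""
        return self._by_signature.get(tuple(bool(v) for v in signature))

    def lookup_pair(self, fluor: FluorCombo, caar: CaarPermutation) -> ColorCode:
        sig = (
            "hmAG3" in fluor.positives,
            "YFP" in fluor.positives,
            "mChEY" in fluor.positives,
            caar.ha,
            caar.cmyc,
            caar.thy,
            True,
        )
        return self._by_signature[sig]

    def match_barcode(self, barcode: str, max_mismatch: int = 1) -> ColorCode | None:
        """Nearest-neighbour barcode match under Hamming distance.

        Returns the unique code within ``max_mismatch`` substitutions, or
        None when no code (or more than one, impossible for registries built
        at pairwise distance >= 2*max_mismatch + 1) qualifies.
        """
        exact = self._by_barcode.get(barcode)
        if exact is not None:
            return exact
        if max_mismatch == 0 or len(barcode) != self.barcode_length:
            return None
        hits = [
            c for c in self.codes if _hamming(barcode, c.dna_barcode) <= max_mismatch
        ]
        return hits[0] if len(hits) == 1 else None

    @property
    def marker_matrix(self) -> pd.DataFrame:
        """48 x 7 boolean table of expected signatures, indexed by bc_id."""
        return pd.DataFrame(
            [expected_signature(c) for c in self.codes],
            index=pd.Index(self.bc_ids, name="bc_id"),
            columns=list(CHANNELS),
        )

    # ---- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bc_id": c.bc_id,
                "fluor": c.fluor.name,
                "ha": c.caar.ha,
                "cmyc": c.caar.cmyc,
                "thy": c.caar.thy,
                "dna_barcode": c.dna_barcode,
                "dhfr": c.dhfr,
            }
            for c in self.codes
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_frame().to_dict(orient="records"), indent=1)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CodeRegistry":
        codes = [
            ColorCode(
                bc_id=int(r.bc_id),
                fluor=FluorCombo[str(r.fluor)],
                caar=CaarPermutation(bool(r.ha), bool(r.cmyc), bool(r.thy)),
                dna_barcode=str(r.dna_barcode),
                dhfr=bool(r.dhfr),
            )
            for r in df.itertuples()
        ]
        return cls(codes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodeRegistry":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_json(cls, path: str | Path) -> "CodeRegistry":
        return cls.from_frame(pd.DataFrame(json.loads(Path(path).read_text())))


def build_registry(
    barcode_length: int = 30,
    seed: int = 0,
    dhfr: bool = True,
    min_barcode_distance: int = 3,
) -> CodeRegistry:
    """Construct the 48-code registry under the canonical numbering.

    Parameters
    ----------
    barcode_length
        Length of each vector's DNA barcode (>= 8). Barcodes are random,
        distinct, and pairwise Hamming distance >= ``min_barcode_distance``
        apart, so single-substitution sequencing errors decode uniquely.
    seed
        Seeds barcode generation; the fluor/CAAR layout is deterministic.
    dhfr
        Whether the vectors carry the DHFR selection cassette (metadata
        consumed by the simulator; detection is identical either way).
    """
    if barcode_length < 8:
        raise RegistryConfigError("barcode_length must be >= 8")
    rng = np.random.default_rng(seed)
    barcodes = _random_barcodes(48, barcode_length, min_barcode_distance, rng)

    codes: list[ColorCode] = []
    bc_id = 1
    for cmyc in (True, False):  # 1-24 cMyc+, 25-48 cMyc-
        caar_block = _caar_block(cmyc)
        for combo in FLUOR_ORDER:
            for caar in caar_block:
                codes.append(
                    ColorCode(
                        bc_id=bc_id,
                        fluor=combo,
                        caar=caar,
                        dna_barcode=barcodes[bc_id - 1],
                        dhfr=dhfr,
                    )
                )
                bc_id += 1
    return CodeRegistry(codes)


def expand_panel(registry: CodeRegistry, clones_per_code: int = 3) -> pd.DataFrame:
    """Enumerate a clone panel: ``clones_per_code`` independently derived
    clonal lines per color code (48 codes x 3 clones = a 144-line panel).

    Returns one row per clonal line with columns ``bc_id``, ``clone`` and
    ``line_id`` (e.g. ``17BC#2``).
    """
    if clones_per_code < 1:
        raise ValueError("clones_per_code must be >= 1")
    rows = [
        {"bc_id": c.bc_id, "clone": k, "line_id": f"{c.bc_id}BC#{k}"}
        for c in registry.codes
        for k in range(1, clones_per_code + 1)
    ]
    return pd.DataFrame(rows)
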