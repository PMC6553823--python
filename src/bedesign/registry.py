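"""Domain types shared by every pipeline stage, the built-in base-editor and
PAM registries, and elementary sequence utilities.

Conventions used throughout the package
---------------------------------------
* Genomic coordinates are 1-based inclusive (GFF3/Ensembl style).
* Spacer positions (activity windows, edited offsets, mismatch offsets) are
  1-based counted from the PAM-distal end of the spacer; for a 3' PAM,
  position 1 is the spacer's 5' terminus.
* Penalties are multipliers in (0, 1]: an ideal guide multiplies nothing
  smaller than 1 into its score.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml
from Bio.Seq import Seq

__all__ = [
    "ContractViolation",
    "ConfigError",
    "BaseEditorSpec",
    "PamSpec",
    "RunConfig",
    "IUPAC_CLASSES",
    "pam_matches",
    "reverse_complement",
    "complement_base",
    "translate_codon",
    "builtin_editors",
    "builtin_pams",
    "editors_to_table",
    "editors_from_table",
    "pams_to_table",
    "pams_from_table",
]

DNA_BASES = frozenset("ACGT")

#: IUPAC nucleotide degeneracy classes.  An observed genome ``N`` is a member
#: of no class: an ambiguous genome base never satisfies a PAM.
IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Complement of an IUPAC symbol (needed to mirror PAM patterns onto the
#: opposite strand).
IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class ContractViolation(ValueError):
    """An operation was called outside its documented preconditions."""


class ConfigError(ValueError):
    """A run configuration or registry entry is invalid."""


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the alphabet {A,C,G,T,N}."""
    bad = set(seq) - frozenset("ACGTN")
    if bad:
        raise ContractViolation(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    """Complement of a single concrete base (N maps to N)."""
    if len(base) != 1 or base not in "ACGTN":
        raise ContractViolation(f"invalid base {base!r}")
    return base.translate(_COMPLEMENT)


def pam_matches(pattern: str, observed: str) -> bool:
    """True iff ``observed`` satisfies the IUPAC-degenerate PAM ``pattern``.

    The comparison is positional: each observed base must belong to the IUPAC
    class of the corresponding pattern symbol.  An observed ``N`` (ambiguous
    genome base) matches nothing.
    """
    if len(pattern) != len(observed):
        raise ContractViolation(
            f"pattern length {len(pattern)} != observed length {len(observed)}"
        )
    for sym, base in zip(pattern, observed):
        try:
            allowed = IUPAC_CLASSES[sym]
        except KeyError:
            raise ContractViolation(f"invalid IUPAC symbol {sym!r} in pattern")
        if base not in allowed:  # genome N falls through here by design
            if base not in "ACGTN":
                raise ContractViolation(f"invalid observed base {base!r}")
            return False
    return True


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code; stop is ``*``."""
    if len(codon) != 3 or any(b not in DNA_BASES for b in codon):
        raise ContractViolation(f"not an unambiguous codon: {codon!r}")
    return str(Seq(codon).translate(table=1))


# ---------------------------------------------------------------------------
# registry types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseEditorSpec:
    """A base editor's conversion chemistry and maximum-activity window.

    ``window_start``/``window_end`` are spacer positions, 1-based from the
    PAM-distal end.  ``compatible_pams`` is advisory only; users may combine
    any editor with any PAM.
    """

    name: str
    source_base: str
    target_base: str
    window_start: int
    window_end: int
    compatible_pams: tuple[str, ...] = ()

    def __post_init__(self):
        if self.source_base not in DNA_BASES or self.target_base not in DNA_BASES:
            raise ConfigError(f"editor {self.name}: bases must be one of A/C/G/T")
        if self.source_base == self.target_base:
            raise ConfigError(f"editor {self.name}: source and target base are equal")
        if not (1 <= self.window_start <= self.window_end):
            raise ConfigError(
                f"editor {self.name}: invalid window "
                f"{self.window_start}..{self.window_end}"
            )


@dataclass(frozen=True)
class PamSpec:
    """An IUPAC PAM pattern and its side relative to the spacer.

    ``three_prime`` means the PAM lies downstream of the spacer's 3' end (the
    SpCas9 NGG geometry); ``five_prime`` means upstream of the 5' end (e.g.
    Cas12a TTTV).
    """

    name: str
    pattern: str
    side: str = "three_prime"

    def __post_init__(self):
        if not self.pattern:
            raise ConfigError(f"PAM {self.name}: empty pattern")
        bad = set(self.pattern) - set(IUPAC_CLASSES)
        if bad:
            raise ConfigError(f"PAM {self.name}: invalid IUPAC symbol(s) {sorted(bad)}")
        if self.side not in ("five_prime", "three_prime"):
            raise ConfigError(f"PAM {self.name}: side must be five_prime|three_prime")

    def __len__(self) -> int:
        return len(self.pattern)


def builtin_editors() -> list[BaseEditorSpec]:
    """Built-in editor defaults (override via config).

    Window bounds follow the primary literature for each enzyme; they are
    defaults, not fixed properties — any chemistry/window can be supplied.
    """
    return [
        BaseEditorSpec("Target-AID", "C", "T", 2, 4, ("NGG", "NG")),
        BaseEditorSpec("BE3", "C", "T", 4, 8, ("NGG",)),
        BaseEditorSpec("ABE7.10", "A", "G", 4, 7, ("NGG",)),
    ]


def builtin_pams() -> list[PamSpec]:
    return [
        PamSpec("NGG", "NGG", "three_prime"),
        PamSpec("NG", "NG", "three_prime"),
    ]


# ---------------------------------------------------------------------------
# registry (de)serialization — tab-separated tables
# ---------------------------------------------------------------------------

def editors_to_table(editors: list[BaseEditorSpec]) -> str:
    df = pd.DataFrame(
        [
            {
                "name": e.name,
                "source_base": e.source_base,
                "target_base": e.target_base,
                "window_start": e.window_start,
                "window_end": e.window_end,
                "compatible_pams": ",".join(e.compatible_pams),
            }
            for e in editors
        ]
    )
    return df.to_csv(sep="\t", index=False)


def editors_from_table(text: str) -> list[BaseEditorSpec]:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    return [
        BaseEditorSpec(
            r["name"],
            r["source_base"],
            r["target_base"],
            int(r["window_start"]),
            int(r["window_end"]),
            tuple(p for p in r.get("compatible_pams", "").split(",") if p),
        )
        for _, r in df.iterrows()
    ]


def pams_to_table(pams: list[PamSpec]) -> str:
    df = pd.DataFrame([{"name": p.name, "pattern": p.pattern, "side": p.side} for p in pams])
    return df.to_csv(sep="\t", index=False)


def pams_from_table(text: str) -> list[PamSpec]:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    return [PamSpec(r["name"], r["pattern"], r["side"]) for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of one design run, loadable from a YAML file."""

    genome_fasta: str = ""
    annotation_gff: str = ""
    mutation_table: str = ""
    editors: list[BaseEditorSpec] = field(default_factory=builtin_editors)
    pams: list[PamSpec] = field(default_factory=builtin_pams)
    guide_length: int = 20
    mutation_format: str = "nucleotide"
    mode: str = "model"
    max_mismatches: int = 2
    penalty_model: "object | None" = None  # scoring.PenaltyModel; default built lazily
    substitution_matrix: list[tuple[str, str]] | None = None
    mutation_class: str = "any"
    random_seed: int = 0

    def __post_init__(self):
        if self.mutation_format not in ("nucleotide", "amino_acid"):
            raise ConfigError(f"mutation_format {self.mutation_format!r} invalid")
        if self.mode not in ("model", "correct"):
            raise ConfigError(f"mode {self.mode!r} invalid")
        if self.mutation_class not in ("any", "nonsynonymous", "synonymous"):
            raise ConfigError(f"mutation_class {self.mutation_class!r} invalid")
        if self.max_mismatches < 0:
            raise ConfigError("max_mismatches must be >= 0")
        if self.guide_length < 1:
            raise ConfigError("guide_length must be >= 1")
        for e in self.editors:
            if e.window_end > self.guide_length:
                raise ConfigError(
                    f"editor {e.name}: window_end {e.window_end} exceeds "
                    f"guide_length {self.guide_length}"
                )

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .scoring import PenaltyModel  # local import to avoid a cycle

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw: dict = {}
        for key in (
            "genome_fasta",
            "annotation_gff",
            "mutation_table",
            "guide_length",
            "mutation_format",
            "mode",
            "max_mismatches",
            "mutation_class",
            "random_seed",
        ):
            if key in raw:
                kw[key] = raw[key]
        if "editors" in raw:
            kw["editors"] = [
                BaseEditorSpec(
                    d["name"],
                    d["source_base"],
                    d["target_base"],
                    int(d["window_start"]),
                    int(d["window_end"]),
                    tuple(d.get("compatible_pams", ())),
                )
                for d in raw["editors"]
            ]
        if "pams" in raw:
            kw["pams"] = [
                PamSpec(d["name"], d["pattern"], d.get("side", "three_prime"))
                for d in raw["pams"]
            ]
        if "substitution_matrix" in raw and raw["substitution_matrix"] is not None:
            kw["substitution_matrix"] = [tuple(p) for p in raw["substitution_matrix"]]
        if "penalty_model" in raw and raw["penalty_model"] is not None:
            kw["penalty_model"] = PenaltyModel.from_dict(raw["penalty_model"])
        return cls(**kw)

    def to_yaml_dict(self) -> dict:
        d: dict = {
            "genome_fasta": self.genome_fasta,
            "annotation_gff": self.annotation_gff,
            "mutation_table": self.mutation_table,
            "guide_length": self.guide_length,
            "mutation_format": self.mutation_format,
            "mode": self.mode,
            "max_mismatches": self.max_mismatches,
            "mutation_class": self.mutation_class,
            "random_seed": self.random_seed,
            "editors": [
                {
                    "name": e.name,
                    "source_base": e.source_base,
                    "target_base": e.target_base,
                    "window_start": e.window_start,
                    "window_end": e.window_end,
                    "compatible_pams": list(e.compatible_pams),
                }
                for e in self.editors
            ],
            "pams": [
                {"name": p.name, "pattern": p.pattern, "side": p.side} for p in self.pams
            ],
        }
        if self.substitution_matrix is not None:
            d["substitution_matrix"] = [list(p) for p in self.substitution_matrix]
        if self.penalty_model is not None:
            d["penalty_model"] = self.penalty_model.to_dict()
        return d
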