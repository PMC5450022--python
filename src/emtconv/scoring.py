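"""EMT and metabolism scores on log₂ expression changes.

All scores share one construction on a signed gene signature:

    score = (Σ log₂FC of up-genes − Σ log₂FC of down-genes) / n_used

where n_used counts the signature genes actually present in the input
(missing genes are excluded from numerator and denominator alike; the
all-genes denominator is selectable). Three variants are provided: a
general signature score (e.g. the up/down-split EMT signature), the
six-gene qPCR EMT score (up: Cdh2, Fn1, Slug, Zeb1; down: Epcam, Ocln),
and the metabolism score contrasting oxidative phosphorylation
(KEGG00190) against glycolysis (KEGG00010) members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd


class MissingGenesError(ValueError):
    """No signature gene is present in the expression changes."""

    def __init__(self, signature: str, missing: Iterable[str]):
        self.signature = signature
        self.missing = sorted(missing)
        super().__init__(
            f"signature {signature!r}: none of its genes are present; "
            f"missing: {', '.join(self.missing)}"
        )


def normalize_symbol(symbol: str, species: str = "human") -> str:
    """Case-normalize a gene symbol: all-upper for human, capitalized
    for mouse."""
    s = symbol.strip()
    if species == "mouse":
        return s[:1].upper() + s[1:].lower()
    return s.upper()


@dataclass
class ExpressionChanges:
    """Gene → log₂ fold change vs control for one sample/timepoint."""

    values: dict[str, float]
    sample: str = ""
    provenance: str = ""        # RNA-seq / microarray / qPCR
    species: str = "human"

    def __post_init__(self) -> None:
        normd: dict[str, float] = {}
        for g, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite log2FC for {g}")
            key = normalize_symbol(g, self.species)
            if key in normd:
                raise ValueError(f"duplicate symbol after normalization: {key}")
            normd[key] = float(v)
        self.values = normd

    def get(self, gene: str) -> Optional[float]:
        return self.values.get(normalize_symbol(gene, self.species))

    @classmethod
    def from_raw(
        cls,
        raw: Mapping[str, float],
        control: Mapping[str, float],
        pseudocount: float = 1.0,
        **kw,
    ) -> "ExpressionChanges":
        """Build from raw (linear) values: log₂((x+ε)/(control+ε)) with
        ε = 1 pseudocount."""
        vals = {
            g: math.log2((raw[g] + pseudocount) / (control[g] + pseudocount))
            for g in raw
            if g in control
        }
        return cls(vals, **kw)


@dataclass(frozen=True)
class SignatureSet:
    """Named up-regulated and down-regulated gene lists."""

    name: str
    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        up = tuple(dict.fromkeys(self.up))
        down = tuple(dict.fromkeys(self.down))
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)
        if set(up) & set(down):
            raise ValueError(f"{self.name}: up and down lists overlap")

    def normalized(self, species: str) -> "SignatureSet":
        return SignatureSet(
            self.name,
            tuple(normalize_symbol(g, species) for g in self.up),
            tuple(normalize_symbol(g, species) for g in self.down),
        )


QPCR_EMT_SIGNATURE = SignatureSet(
    "EMT-qPCR",
    up=("Cdh2", "Fn1", "Slug", "Zeb1"),
    down=("Epcam", "Ocln"),
)

# symbol aliases applied before the qPCR score (Slug's official symbol
# is Snai2; inputs may use either)
DEFAULT_ALIASES = {"SNAI2": "SLUG"}


@dataclass(frozen=True)
class ScoreResult:
    score: float
    n_used: int
    used_up: tuple[str, ...]
    used_down: tuple[str, ...]
    missing: tuple[str, ...]


def signature_score(
    changes: ExpressionChanges,
    sig: SignatureSet,
    *,
    denominator: str = "used",
) -> ScoreResult:
    """Signed signature score.

    ``denominator='used'`` divides by the signature genes present in the
    input (the default reading of "overall number of genes used for
    calculation"); ``denominator='all'`` divides by the full signature
    size regardless of missingness.
    """
    if denominator not in ("used", "all"):
        raise ValueError("denominator must be 'used' or 'all'")
    nsig = sig.normalized(changes.species)
    up_present = [(g, changes.values[g]) for g in nsig.up if g in changes.values]
    down_present = [(g, changes.values[g]) for g in nsig.down if g in changes.values]
    missing = [g for g in (*nsig.up, *nsig.down)
               if g not in changes.values]
    n_used = len(up_present) + len(down_present)
    if n_used == 0:
        raise MissingGenesError(sig.name, missing)
    denom = n_used if denominator == "used" else len(nsig.up) + len(nsig.down)
    score = (sum(v for _, v in up_present) - sum(v for _, v in down_present)) / denom
    return ScoreResult(
        score=score,
        n_used=n_used,
        used_up=tuple(g for g, _ in up_present),
        used_down=tuple(g for g, _ in down_present),
        missing=tuple(missing),
    )


def emt_score_qpcr(
    changes: ExpressionChanges,
    aliases: Optional[Mapping[str, str]] = None,
    **kw,
) -> ScoreResult:
    """Six-gene qPCR EMT score (up: Cdh2, Fn1, Slug, Zeb1; down: Epcam,
    Ocln). Symbol aliases (Snai2 → Slug by default) are applied first."""
    if aliases is None:
        aliases = DEFAULT_ALIASES
    alias_norm = {
        normalize_symbol(k, changes.species): normalize_symbol(v, changes.species)
        for k, v in aliases.items()
    }
    vals: dict[str, float] = {}
    for g, v in changes.values.items():
        tgt = alias_norm.get(g, g)
        if tgt in vals:
            raise ValueError(f"alias collapse collides on {tgt}")
        vals[tgt] = v
    aliased = ExpressionChanges(vals, changes.sample, changes.provenance, changes.species)
    return signature_score(aliased, QPCR_EMT_SIGNATURE, **kw)


def metabolism_score(
    changes: ExpressionChanges,
    ox_set: Iterable[str],
    gly_set: Iterable[str],
    **kw,
) -> ScoreResult:
    """Metabolism score: oxidative phosphorylation (up) against
    glycolysis (down) gene sets."""
    sig = SignatureSet("metabolism-OXvsGly", up=tuple(ox_set), down=tuple(gly_set))
    return signature_score(changes, sig, **kw)


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: one set per line,
    name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def packaged_gene_sets(name: str) -> dict[str, list[str]]:
    """Load a gene-set file shipped with the package
    (``kegg_metabolism_synthetic.gmt`` or ``emt_signature_synthetic.gmt``)."""
    ref = resources.files("emtconv.data") / name
    with resources.as_file(ref) as p:
        return read_gmt(p)


def load_metabolism_sets(path: str | Path | None = None) -> tuple[list[str], list[str]]:
    """(OX, Gly) gene lists from a GMT file; defaults to the shipped
    representative KEGG00190/KEGG00010 member subsets."""
    sets = read_gmt(path) if path else packaged_gene_sets("kegg_metabolism_synthetic.gmt")
    ox = next((v for k, v in sets.items() if "00190" in k), None)
    gly = next((v for k, v in sets.items() if "00010" in k), None)
    if ox is None or gly is None:
        raise ValueError("GMT must contain KEGG00190 and KEGG00010 sets")
    return ox, gly


def load_emt_signature(path: str | Path | None = None) -> SignatureSet:
    """Up/down EMT SignatureSet from a GMT with *_UP and *_DOWN sets;
    defaults to the shipped synthetic stand-in signature."""
    sets = read_gmt(path) if path else packaged_gene_sets("emt_signature_synthetic.gmt")
    up = next((v for k, v in sets.items() if k.upper().endswith("_UP")), None)
    down = next((v for k, v in sets.items() if k.upper().endswith("_DOWN")), None)
    if up is None or down is None:
        raise ValueError("GMT must contain an *_UP and a *_DOWN set")
    return SignatureSet("EMT", up=tuple(up), down=tuple(down))


# ---------------------------------------------------------------- homologs

def homolog_map(
    symbols: Iterable[str],
    table: pd.DataFrame,
    *,
    direction: str = "human_to_mouse",
) -> tuple[dict[str, str], list[str]]:
    """Map gene symbols through a two-column homolog table.

    ``table`` has columns ``human`` and ``mouse``. Returns (mapping of
    the input symbols that were found, list of unmapped symbols —
    reported, never silently dropped). Conflicting duplicate rows raise.
    """
    if direction not in ("human_to_mouse", "mouse_to_human"):
        raise ValueError("bad direction")
    src, dst = ("human", "mouse") if direction == "human_to_mouse" else ("mouse", "human")
    src_species = "human" if src == "human" else "mouse"
    t = table.copy()
    t[src] = [normalize_symbol(s, src_species) for s in t[src]]
    dup = t.groupby(src)[dst].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValueError(f"conflicting homolog rows for: {', '.join(conflicts.index)}")
    lut = dict(zip(t[src], t[dst]))
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for s in symbols:
        key = normalize_symbol(s, src_species)
        if key in lut:
            mapped[s] = lut[key]
        else:
            unmapped.append(s)
    return mapped, unmapped


def load_homolog_table() -> pd.DataFrame:
    """The shipped curated human↔mouse symbol table (covers the genes
    the package's defaults reference)."""
    ref = resources.files("emtconv.data") / "human_mouse_homologs.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
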