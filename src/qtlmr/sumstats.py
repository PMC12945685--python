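"""Summary-statistics containers, I/O and exposure/outcome allele harmonization.

Association tables follow GWAS-SSF-style column naming by default; alternative
layouts are handled through a *dialect* mapping of canonical field names to the
column names found in the file. Variants are restricted to biallelic SNVs with
1-based coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _st

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field -> GWAS-SSF column name
DEFAULT_DIALECT: dict[str, str] = {
    "id": "variant_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "standard_error",
    "eaf": "effect_allele_frequency",
    "p": "p_value",
    "n": "n",
    "n_case": "n_case",
    "n_ctrl": "n_ctrl",
}

_REQUIRED = ("chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p")

#: internal canonical column order used by :class:`SumStats` frames
COLUMNS = [
    "id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "eaf", "p", "n", "n_case", "n_ctrl",
]


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic SNV: id, 1-based position and allele pair."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele identical")
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise ValueError(f"{self.id}: alleles must be single upper-case nucleotides")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G pairs cannot be strand-resolved from alleles alone."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class AssocRecord:
    """One variant-trait association: effect on the effect-allele scale."""

    variant: VariantKey
    beta: float
    se: float
    eaf: float | None = None
    p: float | None = None
    n: int | None = None
    n_case: int | None = None
    n_ctrl: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.variant.id}: se must be positive")
        if self.p is not None and not (0 < self.p <= 1):
            raise ValueError(f"{self.variant.id}: p outside (0, 1]")
        if self.n_case is not None and self.n_ctrl is not None and self.n is not None:
            if self.n != self.n_case + self.n_ctrl:
                raise ValueError(f"{self.variant.id}: n != n_case + n_ctrl")


class TraitRole(str, Enum):
    EXPOSURE = "exposure"
    OUTCOME = "outcome"


@dataclass
class LoadReport:
    """Per-reason counts of rows kept or dropped while reading a table."""

    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_text(self) -> str:
        lines = [f"kept\t{self.n_kept}"]
        lines += [f"dropped:{k}\t{v}" for k, v in sorted(self.dropped.items())]
        return "\n".join(lines) + "\n"


class SumStats:
    """Association records for one trait in one ancestry (and tissue).

    Internally a :class:`pandas.DataFrame` with canonical columns; records are
    unique per :class:`VariantKey`.
    """

    def __init__(
        self,
        trait_id: str,
        trait_role: TraitRole | str,
        df: pd.DataFrame,
        ancestry: str = "NA",
        tissue: str | None = None,
        load_report: LoadReport | None = None,
    ) -> None:
        self.trait_id = trait_id
        self.trait_role = TraitRole(trait_role)
        self.ancestry = ancestry
        self.tissue = tissue
        self.load_report = load_report
        df = df.reset_index(drop=True)
        for c in COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        self.df = df[COLUMNS]
        key = df["id"]
        if key.duplicated().any():
            raise ValueError(f"{trait_id}: duplicate variant keys")

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant: VariantKey) -> bool:
        return variant.id in set(self.df["id"])

    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.id, str(r.chrom), int(r.pos), r.effect_allele, r.other_allele)
            for r in self.df.itertuples()
        ]

    def record(self, variant_id: str) -> AssocRecord:
        row = self.df.loc[self.df["id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return _row_to_record(row.iloc[0])

    def records(self) -> list[AssocRecord]:
        return [_row_to_record(row) for _, row in self.df.iterrows()]

    def subset(self, variant_ids: Iterable[str]) -> "SumStats":
        ids = set(variant_ids)
        return SumStats(
            self.trait_id, self.trait_role,
            self.df[self.df["id"].isin(ids)].copy(),
            ancestry=self.ancestry, tissue=self.tissue,
        )

    def in_window(self, chrom: str, start: int, end: int) -> "SumStats":
        """Records with start <= pos <= end on ``chrom`` (1-based inclusive)."""
        m = (self.df["chrom"].astype(str) == str(chrom)) & self.df["pos"].between(start, end)
        return SumStats(
            self.trait_id, self.trait_role, self.df[m].copy(),
            ancestry=self.ancestry, tissue=self.tissue,
        )


def _row_to_record(row: pd.Series) -> AssocRecord:
    def _opt(v):
        return None if pd.isna(v) else v

    def _opt_int(v):
        return None if pd.isna(v) else int(v)

    vk = VariantKey(row["id"], str(row["chrom"]), int(row["pos"]),
                    row["effect_allele"], row["other_allele"])
    return AssocRecord(
        variant=vk, beta=float(row["beta"]), se=float(row["se"]),
        eaf=_opt(row["eaf"]), p=_opt(row["p"]), n=_opt_int(row["n"]),
        n_case=_opt_int(row["n_case"]), n_ctrl=_opt_int(row["n_ctrl"]),
    )


def records_to_frame(records: Iterable[AssocRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.variant.id, "chrom": r.variant.chrom, "pos": r.variant.pos,
            "effect_allele": r.variant.effect_allele, "other_allele": r.variant.other_allele,
            "beta": r.beta, "se": r.se, "eaf": np.nan if r.eaf is None else r.eaf,
            "p": np.nan if r.p is None else r.p, "n": np.nan if r.n is None else r.n,
            "n_case": np.nan if r.n_case is None else r.n_case,
            "n_ctrl": np.nan if r.n_ctrl is None else r.n_ctrl,
        })
    return pd.DataFrame(rows, columns=COLUMNS)


# ---------------------------------------------------------------------------
# reading / writing


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str = "trait",
    trait_role: TraitRole | str = TraitRole.EXPOSURE,
    ancestry: str = "NA",
    tissue: str | None = None,
) -> SumStats:
    """Read a delimited summary-statistics table, validating each row.

    Rows failing record invariants (non-positive se, bad alleles, invalid p,
    duplicated variant key, ...) are dropped and counted in the attached
    :class:`LoadReport`. Missing p-values are recomputed from beta/se with a
    two-sided normal approximation.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype={dialect["chrom"]: str}, na_values=["NA"])
    missing = [dialect[f] for f in _REQUIRED if dialect[f] not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    report = LoadReport()
    inv = {v: k for k, v in dialect.items()}
    df = raw.rename(columns=inv)
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[COLUMNS].copy()
    if df["id"].isna().all():
        df["id"] = [f"{c}:{int(p)}" for c, p in zip(df["chrom"], df["pos"])]

    # recompute missing p from z (logged)
    miss_p = df["p"].isna() & df["beta"].notna() & (df["se"] > 0)
    if miss_p.any():
        z = df.loc[miss_p, "beta"] / df.loc[miss_p, "se"]
        df.loc[miss_p, "p"] = np.maximum(2 * _st.norm.sf(np.abs(z)), np.finfo(float).tiny)
        logger.info("%s: recomputed %d missing p-values from beta/se", path, int(miss_p.sum()))

    ok = pd.Series(True, index=df.index)

    def _fail(mask, reason):
        nonlocal ok
        bad = mask & ok
        if bad.any():
            report.drop(reason, int(bad.sum()))
            ok &= ~mask

    alleles_ok = (
        df["effect_allele"].isin(_NUCLEOTIDES)
        & df["other_allele"].isin(_NUCLEOTIDES)
        & (df["effect_allele"] != df["other_allele"])
    )
    _fail(~alleles_ok, "bad_alleles")
    _fail(~(df["pos"].notna() & (df["pos"] >= 1)), "bad_position")
    _fail(~(df["se"] > 0), "nonpositive_se")
    _fail(~(df["beta"].notna() & np.isfinite(df["beta"].astype(float))), "missing_beta")
    _fail(~((df["p"] > 0) & (df["p"] <= 1)), "bad_p")
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
    _fail(eaf_bad, "bad_eaf")
    ncc = df["n"].notna() & df["n_case"].notna() & df["n_ctrl"].notna()
    _fail(ncc & (df["n"] != df["n_case"] + df["n_ctrl"]), "n_mismatch")

    df = df[ok].copy()
    dup = df["id"].duplicated()
    if dup.any():
        report.drop("duplicate_variant", int(dup.sum()))
        logger.warning("%s: dropped %d duplicate variant rows", path, int(dup.sum()))
        df = df[~dup]

    if df.empty:
        raise ValueError(f"{path}: zero valid rows after filtering")
    df["pos"] = df["pos"].astype(int)
    report.n_kept = len(df)
    return SumStats(trait_id, trait_role, df, ancestry=ancestry, tissue=tissue,
                    load_report=report)


def write_sumstats(s: SumStats, path) -> None:
    """Write tab-separated GWAS-SSF-style output; round-trips exactly.

    Numeric fields are serialized at 17 significant digits so that
    ``read_sumstats(write_sumstats(s))`` reproduces every float bit-for-bit;
    missing values become the ``NA`` sentinel.
    """
    out = s.df.rename(columns=DEFAULT_DIALECT)

    def _fmt(v):
        if pd.isna(v):
            return "NA"
        if isinstance(v, (int, np.integer)):
            return str(int(v))
        f = float(v)
        return str(int(f)) if f.is_integer() and abs(f) < 1e15 else format(f, ".17g")

    cols = list(out.columns)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_fmt(v) if not isinstance(v, str) else v for v in row) + "\n")


# ---------------------------------------------------------------------------
# harmonization


class HarmonizeStatus(str, Enum):
    KEPT = "kept"
    FLIPPED = "flipped"
    PALINDROMIC_INFERRED = "palindromic_inferred"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_MISMATCH = "dropped_mismatch"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects expressed on the exposure's effect allele."""

    variant: VariantKey
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None
    eaf_y: float | None
    status: HarmonizeStatus

    @property
    def usable(self) -> bool:
        return self.status in (
            HarmonizeStatus.KEPT,
            HarmonizeStatus.FLIPPED,
            HarmonizeStatus.PALINDROMIC_INFERRED,
        )


def harmonize(
    exposure: AssocRecord,
    outcome: AssocRecord,
    palindrome_eaf_limit: float = 0.42,
) -> HarmonizedPair:
    """Align the outcome effect to the exposure's effect allele.

    The outcome beta and EAF are flipped when its effect allele matches the
    exposure's other allele (directly or on the complementary strand).
    Palindromic variants are resolved by effect-allele-frequency concordance
    and dropped when the minor-allele frequency exceeds
    ``palindrome_eaf_limit`` on either side, or when an EAF is missing.
    """
    ev, ov = exposure.variant, outcome.variant
    if ev.locus() != ov.locus():
        raise ValueError("harmonize called on different positions (caller bug)")

    def _pair(beta_y, eaf_y, status):
        return HarmonizedPair(
            variant=ev, beta_x=exposure.beta, se_x=exposure.se,
            beta_y=beta_y, se_y=outcome.se, eaf_x=exposure.eaf, eaf_y=eaf_y,
            status=status,
        )

    def _dropped(status):
        return _pair(outcome.beta, outcome.eaf, status)

    exp_set = {ev.effect_allele, ev.other_allele}
    out_set = {ov.effect_allele, ov.other_allele}
    comp_out = {_COMPLEMENT[a] for a in out_set}

    if ev.is_palindromic:
        if out_set != exp_set:
            return _dropped(HarmonizeStatus.DROPPED_MISMATCH)
        if exposure.eaf is None or outcome.eaf is None:
            return _dropped(HarmonizeStatus.DROPPED_PALINDROMIC)
        # nominal orientation by allele label, then check MAF-side agreement
        if ov.effect_allele == ev.effect_allele:
            beta_y, eaf_y = outcome.beta, outcome.eaf
        else:
            beta_y, eaf_y = -outcome.beta, 1.0 - outcome.eaf
        maf_x = min(exposure.eaf, 1 - exposure.eaf)
        maf_y = min(eaf_y, 1 - eaf_y)
        if maf_x > palindrome_eaf_limit or maf_y > palindrome_eaf_limit:
            return _dropped(HarmonizeStatus.DROPPED_PALINDROMIC)
        if (exposure.eaf < 0.5) != (eaf_y < 0.5):
            # frequencies disagree: the strand is flipped relative to labels
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        return _pair(beta_y, eaf_y, HarmonizeStatus.PALINDROMIC_INFERRED)

    if out_set == exp_set:
        same = ov.effect_allele == ev.effect_allele
    elif comp_out == exp_set:
        same = _COMPLEMENT[ov.effect_allele] == ev.effect_allele
    else:
        return _dropped(HarmonizeStatus.DROPPED_MISMATCH)

    if same:
        return _pair(outcome.beta, outcome.eaf, HarmonizeStatus.KEPT)
    eaf_y = None if outcome.eaf is None else 1.0 - outcome.eaf
    return _pair(-outcome.beta, eaf_y, HarmonizeStatus.FLIPPED)
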