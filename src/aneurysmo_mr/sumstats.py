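"""GWAS summary-statistics containers, I/O, and allele harmonization.

The on-disk dialect is a plain (optionally gzipped) TSV with base columns

    variant_id  chrom  pos  effect_allele  other_allele  eaf

followed, for each trait, by ``beta_<TRAIT>``, ``se_<TRAIT>``,
``pvalue_<TRAIT>`` and optionally ``n_<TRAIT>``.  A single-trait file may
instead use bare ``beta``/``se``/``pvalue``/``n`` columns; the trait name
is then supplied by the reader.  Lipid traits are in mg/dL per effect
allele; the outcome trait is in log-odds.
"""

from __future__ import annotations

import gzip
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

BASE_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]
#: canonical trait ordering used when writing
TRAIT_ORDER = ["LDL_C", "TRL_C", "TG", "APOB", "LPA", "AAA"]
_VALID_ALLELES = {"A", "C", "G", "T"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumstatsError(ValueError):
    """Malformed or inconsistent summary statistics."""


def _trait_cols(trait: str) -> list:
    return [f"beta_{trait}", f"se_{trait}", f"pvalue_{trait}"]


class MultiTraitSumstats:
    """Variant-keyed table of per-trait (beta, se, pvalue) triples, all
    aligned to a single effect allele per variant."""

    def __init__(self, df: pd.DataFrame, units: Optional[Mapping[str, str]] = None,
                 validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.units: Dict[str, str] = dict(units or {})
        #: bookkeeping set by harmonize()
        self.n_palindromic_dropped = 0
        self.n_irreconcilable_dropped = 0
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    @property
    def traits(self) -> list:
        found = []
        for c in self.df.columns:
            if c.startswith("beta_"):
                found.append(c[len("beta_"):])
        return found

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def copy(self) -> "MultiTraitSumstats":
        out = MultiTraitSumstats(self.df.copy(), self.units, validate=False)
        out.n_palindromic_dropped = self.n_palindromic_dropped
        out.n_irreconcilable_dropped = self.n_irreconcilable_dropped
        return out

    def subset(self, variant_ids: Iterable[str]) -> "MultiTraitSumstats":
        ids = set(variant_ids)
        return MultiTraitSumstats(
            self.df[self.df["variant_id"].isin(ids)].copy(), self.units,
            validate=False)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in BASE_COLUMNS if c not in df.columns]
        if missing:
            raise SumstatsError(f"missing required columns: {missing}")
        if not self.traits:
            raise SumstatsError("no trait columns (beta_<TRAIT>) present")
        for t in self.traits:
            for c in _trait_cols(t):
                if c not in df.columns:
                    raise SumstatsError(f"trait {t!r} missing column {c!r}")
        dup = df["variant_id"][df["variant_id"].duplicated()]
        if len(dup):
            raise SumstatsError(
                f"duplicate variant_id values: {sorted(dup.unique())[:10]}")
        bad_rows = []
        eaf = df["eaf"].to_numpy(float)
        pos = df["pos"].to_numpy()
        ea = df["effect_allele"].astype(str)
        oa = df["other_allele"].astype(str)
        for i in range(len(df)):
            row_bad = False
            if not (0.0 < eaf[i] < 1.0):
                row_bad = True
            if pos[i] < 1:
                row_bad = True
            if ea.iloc[i] not in _VALID_ALLELES or oa.iloc[i] not in _VALID_ALLELES \
                    or ea.iloc[i] == oa.iloc[i]:
                row_bad = True
            if row_bad:
                bad_rows.append(i + 1)  # 1-based data rows
        for t in self.traits:
            se = df[f"se_{t}"].to_numpy(float)
            bad_se = np.flatnonzero(~(se > 0)) + 1
            bad_rows.extend(int(r) for r in bad_se)
        if bad_rows:
            raise SumstatsError(
                "invalid rows (1-based, se<=0 / eaf out of (0,1) / bad alleles "
                f"/ pos<1): {sorted(set(bad_rows))[:20]}")

    # ------------------------------------------------------------------
    def write(self, path) -> None:
        """Serialize as TSV (gzip if path ends with .gz), fixed column
        order, floats at 10 significant digits."""
        traits = sorted(self.traits,
                        key=lambda t: (TRAIT_ORDER.index(t) if t in TRAIT_ORDER
                                       else len(TRAIT_ORDER), t))
        cols = list(BASE_COLUMNS)
        for t in traits:
            cols += _trait_cols(t)
            if f"n_{t}" in self.df.columns:
                cols.append(f"n_{t}")
        extra = [c for c in self.df.columns if c not in cols]
        out = self.df[cols + extra]
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path, trait_units: Mapping[str, str]) -> MultiTraitSumstats:
    """Read and validate a summary-statistics TSV.

    ``trait_units`` maps trait name -> unit string.  If the file uses bare
    ``beta``/``se``/``pvalue`` columns, exactly one trait must be given and
    the columns are renamed to the suffixed dialect.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t",
                         dtype={"variant_id": str, "chrom": str,
                                "effect_allele": str, "other_allele": str})
    if "beta" in df.columns:
        if len(trait_units) != 1:
            raise SumstatsError(
                "bare beta/se/pvalue columns require exactly one trait")
        (trait,) = trait_units
        ren = {"beta": f"beta_{trait}", "se": f"se_{trait}",
               "pvalue": f"pvalue_{trait}"}
        if "n" in df.columns:
            ren["n"] = f"n_{trait}"
        df = df.rename(columns=ren)
    return MultiTraitSumstats(df, units=trait_units)


# ----------------------------------------------------------------------
def _is_palindromic(ea: pd.Series, oa: pd.Series) -> np.ndarray:
    return np.fromiter(((a, b) in _PALINDROMIC for a, b in zip(ea, oa)),
                       dtype=bool, count=len(ea))


def harmonize(exposure: MultiTraitSumstats,
              outcome: MultiTraitSumstats) -> MultiTraitSumstats:
    """Align outcome summary statistics to the exposure's effect alleles.

    Variants are intersected on ``variant_id``.  Where the outcome's
    effect allele equals the exposure's other allele, outcome betas are
    sign-flipped and its EAF complemented.  Strand-ambiguous palindromic
    variants (A/T, C/G) are dropped and counted, as are variants whose
    allele pairs cannot be reconciled.
    """
    new_traits = [t for t in outcome.traits if t not in exposure.traits]
    edf = exposure.df
    keep_cols = ["variant_id", "effect_allele", "other_allele"]
    for t in outcome.traits:
        keep_cols += _trait_cols(t)
        if f"n_{t}" in outcome.df.columns:
            keep_cols.append(f"n_{t}")
    odf = outcome.df[keep_cols].rename(
        columns={"effect_allele": "ea_out", "other_allele": "oa_out"})
    merged = edf.merge(odf, on="variant_id", how="inner",
                       suffixes=("", "_outdup"))

    palindromic = _is_palindromic(merged["effect_allele"], merged["other_allele"])
    same = (merged["ea_out"] == merged["effect_allele"]) & \
           (merged["oa_out"] == merged["other_allele"])
    swapped = (merged["ea_out"] == merged["other_allele"]) & \
              (merged["oa_out"] == merged["effect_allele"])
    irreconcilable = ~(same | swapped)

    n_pal = int(palindromic.sum())
    n_irr = int((irreconcilable & ~palindromic).sum())
    keep = ~(palindromic | irreconcilable)
    merged = merged.loc[keep].reset_index(drop=True)
    flip = swapped.loc[keep].to_numpy()

    for t in new_traits:
        merged.loc[flip, f"beta_{t}"] = -merged.loc[flip, f"beta_{t}"]
    merged = merged.drop(columns=["ea_out", "oa_out"])
    merged = merged.drop(columns=[c for c in merged.columns
                                  if c.endswith("_outdup")])

    units = dict(exposure.units)
    units.update({t: outcome.units.get(t, "") for t in new_traits})
    out = MultiTraitSumstats(merged, units=units, validate=False)
    out.n_palindromic_dropped = n_pal
    out.n_irreconcilable_dropped = n_irr
    return out


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def orient_to_raising_allele(ms: MultiTraitSumstats,
                             anchor_trait: Optional[str] = None
                             ) -> MultiTraitSumstats:
    """Re-orient every variant so the anchor-trait effect is >= 0.

    By default the anchor is the non-HDL-C effect, beta_LDL_C +
    beta_TRL_C.  Flipping a variant negates every trait's beta, swaps the
    alleles and complements the EAF, so |beta| per trait and all
    between-trait ratios are preserved.  Variants whose anchor beta is
    exactly zero are left as-is and flagged in column ``orient_flagged``.
    """
    df = ms.df.copy()
    if anchor_trait is None:
        if not {"beta_LDL_C", "beta_TRL_C"} <= set(df.columns):
            raise SumstatsError(
                "default anchor needs beta_LDL_C and beta_TRL_C columns")
        anchor = df["beta_LDL_C"].to_numpy(float) + df["beta_TRL_C"].to_numpy(float)
    else:
        anchor = df[f"beta_{anchor_trait}"].to_numpy(float)

    flip = anchor < 0
    flagged = anchor == 0
    for t in ms.traits:
        col = f"beta_{t}"
        df.loc[flip, col] = -df.loc[flip, col]
    ea = df["effect_allele"].copy()
    df.loc[flip, "effect_allele"] = df.loc[flip, "other_allele"]
    df.loc[flip, "other_allele"] = ea[flip]
    df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    df["orient_flagged"] = flagged

    out = MultiTraitSumstats(df, units=ms.units, validate=False)
    out.n_palindromic_dropped = ms.n_palindromic_dropped
    out.n_irreconcilable_dropped = ms.n_irreconcilable_dropped
    return out
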