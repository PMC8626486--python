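"""Genetic risk scores and the GRS strata used to split trajectories.

The GRS is the number of risk alleles weighted by log odds ratios,
summed over a panel of common PD risk SNPs (45 by default).  The
weights are external (meta-analysis log-ORs); missing genotypes are
skipped and reported.  Strata are a median split or quartiles with
boundary ties assigned to the lower stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PANEL_SIZE = 45


def read_genotypes(path, delimiter: str = ",") -> pd.DataFrame:
    """Subjects × SNPs risk-allele-count matrix from delimited text.

    First column is the subject id; remaining columns are SNP ids with
    counts in {0, 1, 2} (empty = missing).
    """
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_weights(path, delimiter: str = ",") -> pd.DataFrame:
    """Panel definition table: columns ``snp``, optional ``risk_allele``,
    and ``log_or`` (natural-log odds ratios)."""
    df = pd.read_csv(path, sep=delimiter)
    missing = {"snp", "log_or"} - set(df.columns)
    if missing:
        raise ValueError(f"weights table missing column(s): {sorted(missing)}")
    return df


@dataclass
class GrsProfile:
    subject_id: str
    grs: float
    n_snps_used: int
    missing_snps: list[str]


def compute_grs(genotypes: pd.DataFrame, weights: pd.DataFrame | pd.Series,
                log_base: float | None = None,
                normalize_by_used: bool = False) -> list[GrsProfile]:
    """Per-subject weighted risk-allele count.

    ``genotypes``: subjects × SNPs matrix of counts in {0, 1, 2} (NaN =
    missing).  ``weights``: Series indexed by SNP id, or a DataFrame
    with ``snp`` and ``log_or`` columns, on the natural-log scale;
    ``log_base`` converts from another base.  ``normalize_by_used``
    divides by the number of non-missing SNPs (sensitivity variant; the
    default is the plain weighted count).
    """
    if isinstance(weights, pd.DataFrame):
        weights = weights.set_index("snp")["log_or"]
    missing_w = [s for s in genotypes.columns if s not in weights.index]
    if missing_w:
        raise ValueError(
            f"SNP(s) absent from the weights table: {', '.join(map(str, missing_w))}"
        )
    vals = genotypes.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        bad = np.argwhere(~ok)[0]
        raise ValueError(
            f"allele count outside {{0,1,2}} at subject "
            f"{genotypes.index[bad[0]]!r}, SNP {genotypes.columns[bad[1]]!r}"
        )
    w = weights.loc[genotypes.columns].to_numpy(dtype=float)
    if log_base is not None:
        w = w * np.log(log_base)
    profiles = []
    for sid, row in zip(genotypes.index, vals):
        present = ~np.isnan(row)
        score = float(np.nansum(row[present] * w[present]))
        if normalize_by_used and present.sum():
            score /= present.sum()
        profiles.append(GrsProfile(
            subject_id=str(sid),
            grs=score,
            n_snps_used=int(present.sum()),
            missing_snps=[c for c, p in zip(genotypes.columns, present) if not p],
        ))
    return profiles


def stratify_by_grs(profiles, scheme: str = "median_split") -> pd.Series:
    """Deterministic GRS strata: ``median_split`` or ``quartiles``.

    Boundary ties go to the lower stratum.  Labels are ``low``/``high``
    for the median split and ``Q1``…``Q4`` for quartiles.  All-equal
    scores leave the strata undefined and raise ``ValueError``.
    """
    if hasattr(profiles[0], "grs"):
        scores = pd.Series({p.subject_id: p.grs for p in profiles})
    else:
        scores = pd.Series(profiles, dtype=float)
    if scores.nunique() <= 1:
        raise ValueError("all GRS values are equal; strata are undefined")
    if scheme == "median_split":
        med = float(scores.median())
        return pd.Series(
            np.where(scores <= med, "low", "high"), index=scores.index)
    if scheme == "quartiles":
        if len(scores) < 4:
            raise ValueError("need >= 4 subjects for quartiles")
        q = np.percentile(scores.to_numpy(), [25, 50, 75])
        labels = np.full(len(scores), "Q4", dtype=object)
        vals = scores.to_numpy()
        labels[vals <= q[2]] = "Q3"
        labels[vals <= q[1]] = "Q2"
        labels[vals <= q[0]] = "Q1"
        return pd.Series(labels, index=scores.index)
    raise ValueError(f"unknown scheme {scheme!r}")


def grs_aao_association(profiles, aaos) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) between GRS and age at onset."""
    if hasattr(profiles[0], "grs"):
        x = np.array([p.grs for p in profiles], float)
    else:
        x = np.asarray(profiles, float)
    y = np.asarray(aaos, float)
    if x.shape != y.shape:
        raise ValueError("GRS and AAO vectors must be paired and complete")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
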