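"""Enamel-hypoplasia records, prevalence summaries and group contrasts.

Enamel hypoplasia is a permanent developmental enamel defect (linear
furrow, pit, or aplasia in the FDI typology) recording physiological
stress during crown formation.  The unit of prevalence here is the
tooth: a tooth is affected iff it carries at least one defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from paleodent.datamodel import Biozone, BiozoneInterval, ValidationError

DEFECT_TYPES = ("linear", "pit", "aplasia")


@dataclass(frozen=True)
class Defect:
    """One hypoplastic defect on a tooth crown."""

    type: str
    distance_to_edj_mm: float = 0.0
    defect_width_mm: float | None = None
    severity: int = 1
    crown_localization: str = ""
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.type not in DEFECT_TYPES:
            raise ValidationError(f"defect type {self.type!r} not in {DEFECT_TYPES}")
        if self.distance_to_edj_mm < 0:
            raise ValidationError("distance to EDJ must be >= 0")
        if self.multiplicity < 1:
            raise ValidationError("multiplicity must be >= 1")


@dataclass(frozen=True)
class HypoplasiaRecord:
    specimen_id: str
    species: str
    locality: str
    biozone: str
    defects: tuple[Defect, ...] = ()
    genus: str = ""

    @property
    def affected(self) -> bool:
        return len(self.defects) > 0


@dataclass(frozen=True)
class PrevalenceSummary:
    group: str
    affected: int
    total: int

    @property
    def prevalence(self) -> float:
        """Percentage of affected teeth, in [0, 100]."""
        return 100.0 * self.affected / self.total


def _as_frame(records: Iterable[HypoplasiaRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "affected" not in df.columns:
            raise ValidationError("hypoplasia table needs an 'affected' column")
        df["affected"] = df["affected"].map(_parse_bool)
        if "genus" not in df.columns:
            df["genus"] = df["species"].astype(str).str.split().str[0]
        return df
    rows = [{"specimen_id": r.specimen_id, "species": r.species,
             "genus": r.genus or r.species.split()[0],
             "locality": r.locality, "biozone": r.biozone,
             "affected": r.affected} for r in records]
    return pd.DataFrame(rows)


def _parse_bool(v: object) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise ValidationError(f"unparseable affected flag {v!r}")


def prevalence(records: Iterable[HypoplasiaRecord] | pd.DataFrame,
               group_by: str = "species") -> list[PrevalenceSummary]:
    """Affected/total counts and percentage per group.

    ``group_by`` may be any record column (``species``, ``genus``,
    ``locality``, ``biozone``) or ``"overall"`` for a single pooled
    summary.  Empty input yields an empty list.
    """
    df = _as_frame(records)
    if df.empty:
        return []
    if group_by == "overall":
        return [PrevalenceSummary("overall", int(df["affected"].sum()), len(df))]
    if group_by not in df.columns:
        raise ValidationError(f"cannot group by {group_by!r}")
    out = []
    for key, grp in df.groupby(group_by, sort=True):
        out.append(PrevalenceSummary(str(key), int(grp["affected"].sum()), len(grp)))
    return out


#: epoch assignment per biozone; a cross-boundary interval goes to the
#: transitional group under the default policy
OLIGOCENE = frozenset({Biozone.MP28, Biozone.MP29, Biozone.MP30})
MIOCENE = frozenset({Biozone.MN1, Biozone.MN2, Biozone.MN3})

EPOCHS = ("Oligocene", "transitional", "Miocene")


def epoch_of(biozone: str | BiozoneInterval,
             transitional_as: str = "transitional") -> str:
    """Map a biozone (or interval) to Oligocene / transitional / Miocene."""
    iv = biozone if isinstance(biozone, BiozoneInterval) else BiozoneInterval.parse(str(biozone))
    if iv.start in OLIGOCENE and iv.end in OLIGOCENE:
        return "Oligocene"
    if iv.start in MIOCENE and iv.end in MIOCENE:
        return "Miocene"
    return transitional_as


def epoch_partition(records: Iterable[HypoplasiaRecord] | pd.DataFrame,
                    transitional_as: str = "transitional") -> list[PrevalenceSummary]:
    """Prevalence per epoch with cross-boundary localities kept apart.

    ``transitional_as`` may reassign the straddling group to
    ``"Oligocene"`` or ``"Miocene"`` instead of its own bucket.
    """
    df = _as_frame(records)
    if df.empty:
        return []
    if df["biozone"].astype(str).str.len().eq(0).any():
        raise ValidationError("record without a biozone")
    df["epoch"] = [epoch_of(z, transitional_as) for z in df["biozone"]]
    return prevalence(df, group_by="epoch")


def contingency_by_epoch(records: Iterable[HypoplasiaRecord] | pd.DataFrame) -> pd.DataFrame:
    """Epoch × (affected, unaffected) count table, epochs in time order."""
    summaries = {s.group: s for s in epoch_partition(records)}
    rows = [(s.affected, s.total - s.affected)
            for e in EPOCHS if (s := summaries.get(e)) is not None]
    index = [e for e in EPOCHS if e in summaries]
    return pd.DataFrame(rows, index=index, columns=["affected", "unaffected"])


def chi2_independence(table: Sequence[Sequence[float]] | pd.DataFrame
                      ) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r×c count table.

    No continuity correction is applied (the classical statistic, also
    for 2×2 tables).  Returns (statistic, dof, p).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValidationError("negative cell count")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("zero row/column margin")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def pairwise_wilcoxon(records: Iterable[HypoplasiaRecord] | pd.DataFrame,
                      group_by: str = "biozone") -> pd.DataFrame:
    """Pairwise rank-sum contrasts on per-tooth binary outcomes.

    Returns a long-format frame (group_a, group_b, p_raw, p_holm).
    Raw p-values are the reproduction default; Holm-adjusted ones are
    provided alongside.
    """
    from paleodent import stats as pstats

    df = _as_frame(records)
    groups = {str(k): g["affected"].astype(float).to_numpy()
              for k, g in df.groupby(group_by, sort=True)}
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = pstats.wilcoxon_rank_sum(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "p_raw": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = _holm(out["p_raw"].to_numpy())
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
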