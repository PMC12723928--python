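"""Tumor-antigen prioritization and single-cell specificity scoring.

The prioritization cascade turns peptide-by-sample RPHM matrices into
TSA/TAA calls. Expression thresholds are derived from normal-tissue
cohorts: per peptide, RPHM values are averaged across normal samples with
non-zero expression; peptides are stratified by MHC class and length; and
the 1st percentile of the averages within each stratum defines the
"negligible expression" cutoff for that stratum. A candidate must then
exceed the cutoff in at least one tumor sample, be rare among other-tissue
normals (oGTEx), show no expression above the cutoff in tissues implying
immune tolerance (NAT, mTEC), and is called a tumor-specific antigen (TSA)
when almost no oGTEx sample expresses it, or a tumor-associated antigen
(TAA) when tumor expression exceeds the normal maximum.

The single-cell scorer ranks peptides (and their source genes) by
cell-type specificity of expression using the per-type proportion of
expressing cells and a median-centered coefficient of variation (mCV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_LOW_TUMOR",
    "STATUS_OGTEX",
    "STATUS_TOLERANCE",
    "STATUS_TSA",
    "STATUS_TAA",
    "STATUS_PROTEIN",
    "PrioritizeConfig",
    "ThresholdTable",
    "average_nonzero_rphm",
    "compute_thresholds",
    "prioritize",
    "evaluate_specificity",
    "median_centered_cv",
    "cell_specificity",
]

STATUS_LOW_TUMOR = "excluded_low_tumor"
STATUS_OGTEX = "excluded_oGTEx_recurrent"
STATUS_TOLERANCE = "excluded_tolerance"
STATUS_TSA = "TSA"
STATUS_TAA = "TAA"
STATUS_PROTEIN = "excluded_protein_evidence"


@dataclass
class PrioritizeConfig:
    """Cascade parameters.

    ``ogtex_recurrence_frac`` — a peptide expressed above threshold in more
    than ``floor(frac * n_oGTEx)`` oGTEx samples is excluded as recurrent
    (1% of 2,303 samples gives the "more than 23" rule).
    ``tsa_frac`` — TSA requires strictly fewer than ``frac * n_oGTEx``
    above-threshold oGTEx samples (0.1% of 2,303 gives "fewer than 3").
    """

    percentile: float = 1.0
    ogtex_recurrence_frac: float = 0.01
    tsa_frac: float = 0.001
    exclude_peptides: frozenset[str] = field(default_factory=frozenset)
    min_group_size: int = 100


class ThresholdTable:
    """(MHC class, peptide length) -> RPHM cutoff."""

    def __init__(self, thresholds: Mapping[tuple[str, int], float]) -> None:
        for key, value in thresholds.items():
            if value < 0:
                raise ValueError(f"negative threshold for {key}")
        self._table = dict(thresholds)

    def __getitem__(self, key: tuple[str, int]) -> float:
        try:
            return self._table[key]
        except KeyError:
            raise KeyError(
                f"no threshold for (class, length) group {key}"
            ) from None

    def items(self):
        return self._table.items()

    def per_peptide(self, peptide_meta: pd.DataFrame) -> pd.Series:
        """Threshold for every peptide in a metadata frame.

        ``peptide_meta`` must have columns ``mhc_class`` and ``length``,
        indexed by peptide id.
        """
        missing = []
        out = []
        for pid, row in peptide_meta.iterrows():
            key = (row["mhc_class"], int(row["length"]))
            if key not in self._table:
                missing.append(key)
                out.append(np.nan)
            else:
                out.append(self._table[key])
        if missing:
            raise KeyError(f"no threshold for groups: {sorted(set(missing))}")
        return pd.Series(out, index=peptide_meta.index, name="threshold")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mhc_class": c, "length": l, "threshold": t}
            for (c, l), t in sorted(self._table.items())
        ]
        return pd.DataFrame(rows)


def average_nonzero_rphm(row: Iterable[float]) -> float:
    """Mean over strictly positive entries; 0.0 for an all-zero row."""
    arr = np.asarray(list(row) if not isinstance(row, np.ndarray) else row,
                     dtype=float)
    pos = arr[arr > 0]
    return float(pos.mean()) if pos.size else 0.0


def compute_thresholds(
    normals: pd.DataFrame,
    peptide_meta: pd.DataFrame,
    percentile: float = 1.0,
    min_group_size: int = 100,
) -> ThresholdTable:
    """Stratified RPHM cutoffs from a normal-tissue matrix.

    ``normals`` is peptides x samples (RPHM); ``peptide_meta`` provides
    ``mhc_class`` and ``length`` per peptide. The cutoff of each
    (class, length) group is the ``percentile``-th percentile (linear
    interpolation between order statistics) of per-peptide non-zero-mean
    RPHM values. Groups smaller than ``min_group_size`` fall back to the
    pooled per-class percentile, with a warning — a 1st percentile of a
    handful of peptides is not stable.
    """
    if normals.empty:
        raise ValueError("empty expression matrix")
    averages = pd.Series(
        {pid: average_nonzero_rphm(normals.loc[pid].to_numpy())
         for pid in normals.index},
        name="avg_rphm",
    )
    meta = peptide_meta.loc[normals.index]
    table: dict[tuple[str, int], float] = {}
    pooled_by_class = {
        cls: float(np.percentile(averages[meta["mhc_class"] == cls], percentile))
        for cls in meta["mhc_class"].unique()
    }
    for (cls, length), group in meta.groupby(["mhc_class", "length"]):
        vals = averages.loc[group.index].to_numpy()
        if vals.size < min_group_size:
            warnings.warn(
                f"group ({cls}, {length}) has only {vals.size} peptides; "
                f"using the pooled class-{cls} percentile",
                stacklevel=2,
            )
            table[(cls, int(length))] = pooled_by_class[cls]
        else:
            table[(cls, int(length))] = float(np.percentile(vals, percentile))
    return ThresholdTable(table)


def prioritize(
    tumor: pd.DataFrame,
    nat: pd.DataFrame,
    ogtex: pd.DataFrame,
    mtec: pd.DataFrame,
    thresholds: ThresholdTable,
    peptide_meta: pd.DataFrame,
    cfg: PrioritizeConfig | None = None,
) -> pd.DataFrame:
    """Run the exclusion cascade and return one status per peptide.

    All matrices are peptides x samples and must share the peptide index.
    Steps, in order: (1) require the tumor maximum to exceed the stratum
    threshold; (2) exclude peptides above threshold in more than
    ``floor(frac * n_oGTEx)`` oGTEx samples; (3) exclude peptides above
    threshold in any NAT or mTEC sample (central/peripheral tolerance);
    (4) TSA when strictly fewer than ``tsa_frac * n_oGTEx`` oGTEx samples
    are above threshold; (5) else TAA when the tumor maximum exceeds the
    oGTEx maximum, otherwise excluded as recurrent; (6) peptides on the
    protein-evidence exclusion list are moved to
    ``excluded_protein_evidence``.
    """
    cfg = cfg or PrioritizeConfig()
    peptides = tumor.index
    for other in (nat, ogtex, mtec):
        if not peptides.equals(other.index):
            raise ValueError("expression matrices must share the peptide index")
    thr = thresholds.per_peptide(peptide_meta.loc[peptides])
    max_tumor = tumor.max(axis=1)
    max_nat = nat.max(axis=1) if nat.shape[1] else pd.Series(0.0, index=peptides)
    max_mtec = mtec.max(axis=1) if mtec.shape[1] else pd.Series(0.0, index=peptides)
    max_ogtex = ogtex.max(axis=1)
    n_ogtex = ogtex.shape[1]
    n_above = ogtex.gt(thr, axis=0).sum(axis=1)

    recurrence_cutoff = math.floor(cfg.ogtex_recurrence_frac * n_ogtex)
    tsa_cutoff = cfg.tsa_frac * n_ogtex

    status = np.select(
        [
            ~(max_tumor > thr),
            n_above > recurrence_cutoff,
            (max_nat > thr) | (max_mtec > thr),
            n_above < tsa_cutoff,
            max_tumor > max_ogtex,
        ],
        [STATUS_LOW_TUMOR, STATUS_OGTEX, STATUS_TOLERANCE, STATUS_TSA, STATUS_TAA],
        default=STATUS_OGTEX,
    )
    result = pd.DataFrame(
        {
            "status": status,
            "threshold": thr,
            "max_tumor_rphm": max_tumor,
            "n_ogtex_above": n_above,
            "max_ogtex_rphm": max_ogtex,
            "max_nat_rphm": max_nat,
            "max_mtec_rphm": max_mtec,
        },
        index=peptides,
    )
    if cfg.exclude_peptides:
        hit = result.index.isin(cfg.exclude_peptides) & result["status"].isin(
            [STATUS_TSA, STATUS_TAA]
        )
        result.loc[hit, "status"] = STATUS_PROTEIN
    return result


def evaluate_specificity(
    positives: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame],
    negatives: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame],
    thresholds: ThresholdTable,
    positive_meta: pd.DataFrame,
    negative_meta: pd.DataFrame,
    cfg: PrioritizeConfig | None = None,
) -> tuple[float, float]:
    """Retention of labeled positives and exclusion of labeled negatives.

    Each labeled set is a (tumor, nat, ogtex, mtec) matrix tuple. Returns
    (fraction of positives called TSA/TAA, fraction of negatives
    excluded). An empty set yields NaN with a warning.
    """

    def _frac(matrices, meta, want_retained: bool) -> float:
        if matrices[0].shape[0] == 0:
            warnings.warn("empty peptide set; fraction undefined", stacklevel=3)
            return float("nan")
        res = prioritize(*matrices, thresholds, meta, cfg)
        retained = res["status"].isin([STATUS_TSA, STATUS_TAA])
        return float(retained.mean() if want_retained else (~retained).mean())

    return (_frac(positives, positive_meta, True),
            _frac(negatives, negative_meta, False))


def median_centered_cv(proportions: Iterable[float]) -> float:
    """Sample standard deviation divided by the median.

    A coefficient of variation with the median replacing the mean; a
    median of zero with positive spread scores +inf (maximally specific).
    """
    arr = np.asarray(list(proportions), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two cell types")
    sd = float(arr.std(ddof=1))
    med = float(np.median(arr))
    if med == 0.0:
        return math.inf if sd > 0 else 0.0
    return sd / med


def cell_specificity(
    counts: pd.DataFrame,
    cell_types: Mapping[str, str] | pd.Series,
    cell_samples: Mapping[str, str] | pd.Series | None = None,
    peptide_genes: Mapping[str, str] | pd.Series | None = None,
    top_fraction: float = 0.10,
    min_proportion: float = 0.5,
    top_k: int = 50,
) -> pd.DataFrame:
    """Rank peptides (or genes) by cell-type specificity.

    ``counts`` is peptides x cells (raw matched-read counts);
    ``cell_types`` maps each cell to its type. Per sample, the top
    ``top_fraction`` of detected peptides by normalized abundance are
    kept; the per-type proportion of expressing cells (scProportion) is
    computed for those; peptides expressed in more than ``min_proportion``
    of cells of at least one type are scored by mCV; when a
    peptide-to-gene map is given, each gene is represented by its
    highest-mCV peptide. Returns the ``top_k`` rows sorted by descending
    mCV.
    """
    types = pd.Series(cell_types)
    types = types.loc[counts.columns]
    if types.nunique() < 2:
        raise ValueError("at least two cell types are required")
    if cell_samples is None:
        samples = pd.Series("sample1", index=counts.columns)
    else:
        samples = pd.Series(cell_samples).loc[counts.columns]

    # step 1: per-sample top fraction by normalized abundance
    selected: set[str] = set()
    for sample, cells in counts.columns.to_series().groupby(samples):
        sub = counts[cells]
        total = sub.to_numpy().sum()
        if total == 0:
            continue
        abundance = sub.sum(axis=1) / total * 1e8
        detected = abundance[abundance > 0].sort_values(
            ascending=False, kind="mergesort"
        )
        n_keep = max(1, math.ceil(top_fraction * detected.size))
        selected.update(detected.index[:n_keep])
    if not selected:
        return pd.DataFrame(
            columns=["gene", "peptide", "mcv", "max_proportion"]
        )
    kept = counts.loc[sorted(selected)]

    # steps 2-4: per-type expressing-cell proportions and mCV
    expressing = kept.gt(0)
    proportions = expressing.T.groupby(types).mean().T  # peptides x types
    passing = proportions.max(axis=1) > min_proportion
    proportions = proportions.loc[passing]
    if proportions.empty:
        return pd.DataFrame(columns=["gene", "peptide", "mcv", "max_proportion"])
    mcv = proportions.apply(lambda r: median_centered_cv(r.to_numpy()), axis=1)

    result = pd.DataFrame(
        {
            "peptide": proportions.index,
            "mcv": mcv.to_numpy(),
            "max_proportion": proportions.max(axis=1).to_numpy(),
        }
    )
    if peptide_genes is not None:
        genes = pd.Series(peptide_genes)
        result["gene"] = genes.reindex(result["peptide"]).fillna("").to_numpy()
        # gene-level mCV: the gene's best peptide represents it
        result = (
            result.sort_values(["mcv", "peptide"], ascending=[False, True])
            .groupby("gene", sort=False)
            .head(1)
        )
    else:
        result["gene"] = result["peptide"]
    result = result.sort_values(
        ["mcv", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return result[["gene", "peptide", "mcv", "max_proportion"]].head(top_k)
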