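"""Spike-in normalization and protein-group abundance aggregation.

Raw run-level abundances are rescaled so that the spiked yeast enolase
peptide has the same abundance in every run: for run *r* with spike
abundance ``s_r`` and reference ``S`` (the median spike abundance across
runs by default), every abundance in run *r* is multiplied by
``S / s_r``.  Between-sample abundance ratios are invariant to the
choice of ``S``.

Abundance matrices are DataFrames with features (peptides or group lead
accessions) as the index and runs or samples as columns; missing values
stay missing (no zero imputation) until the multivariate stage.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curation import ProteinGroup, ReplicateDesign

#: most intense peptide of the yeast enolase digestion control
ENOLASE_SPIKE = "DSRGNPTVEVELTTEKGVF"


def normalize_to_spike(
    obs: pd.DataFrame,
    spike_peptide: str = ENOLASE_SPIKE,
    reference: float | str = "median_across_runs",
) -> pd.DataFrame:
    """Renormalize raw abundances to the spiked control peptide.

    Adds a ``normalized_abundance`` column.  ``reference`` is either
    ``"median_across_runs"`` (default) or a fixed positive value ``S``.

    Raises
    ------
    ValueError
        If the spike peptide is missing, or has zero abundance, in any
        run present in ``obs`` (the offending run is named).
    """
    runs = sorted(obs["run_id"].unique())
    spike = obs[obs["peptide"] == spike_peptide].groupby("run_id")["raw_abundance"].sum()
    for run in runs:
        if run not in spike.index or spike.loc[run] <= 0:
            raise ValueError(
                f"spike peptide {spike_peptide!r} missing or zero in run {run!r}"
            )
    if reference == "median_across_runs":
        ref = float(np.median(spike.loc[runs]))
    else:
        ref = float(reference)
        if ref <= 0:
            raise ValueError("fixed reference must be positive")
    factors = ref / spike
    out = obs.copy()
    out["normalized_abundance"] = out["raw_abundance"] * out["run_id"].map(factors)
    return out


def peptide_sample_abundance(
    obs: pd.DataFrame, design: ReplicateDesign
) -> pd.DataFrame:
    """Peptide x sample matrix of normalized abundances.

    A peptide's sample abundance is the mean of its normalized abundance
    over the runs of that sample in which it was observed.
    """
    df = obs.assign(sample_id=obs["run_id"].map(design.sample_of))
    mat = (
        df.groupby(["peptide", "sample_id"])["normalized_abundance"]
        .mean()
        .unstack("sample_id")
    )
    return mat.reindex(columns=[s for s in design.sample_ids if s in mat.columns])


def group_abundance(
    obs: pd.DataFrame,
    groups: Sequence[ProteinGroup],
    design: ReplicateDesign | None = None,
    method: str = "sum_unique",
    n: int = 3,
    level: str = "run",
) -> pd.DataFrame:
    """Aggregate normalized peptide abundances to protein groups.

    ``sum_unique`` sums the group's unique peptides per run; ``topN``
    sums only the ``n`` most abundant unique peptides (Hi-N style).
    ``level="sample"`` averages run-level values within each sample
    (requires ``design``).  Groups with no unique peptides are all-NaN.
    """
    if method not in {"sum_unique", "topN"}:
        raise ValueError(f"unknown aggregation method {method!r}")
    if not groups:
        raise ValueError("no protein groups supplied")
    if level not in {"run", "sample"}:
        raise ValueError(f"unknown level {level!r}")
    if level == "sample" and design is None:
        raise ValueError("level='sample' requires a replicate design")

    runs = sorted(obs["run_id"].unique()) if design is None else design.run_ids
    rows = {}
    by_run = obs.groupby("run_id")
    for g in groups:
        if not g.unique_peptides:
            rows[g.lead_accession] = pd.Series(np.nan, index=runs)
            continue
        vals = {}
        for run in runs:
            try:
                sub = by_run.get_group(run)
            except KeyError:
                vals[run] = 0.0
                continue
            pep_vals = (
                sub[sub["peptide"].isin(g.unique_peptides)]
                .groupby("peptide")["normalized_abundance"]
                .sum()
            )
            if method == "topN":
                pep_vals = pep_vals.nlargest(n)
            vals[run] = float(pep_vals.sum())
        rows[g.lead_accession] = pd.Series(vals).reindex(runs)
    mat = pd.DataFrame(rows).T
    mat.index.name = "lead_accession"
    if level == "sample":
        assert design is not None
        sample_of = {r: design.sample_of(r) for r in runs}
        mat = mat.T.groupby(mat.columns.map(sample_of)).mean().T
        mat = mat.reindex(columns=design.sample_ids)
    return mat


def abundance_rank_curve(
    matrix: pd.DataFrame, highlight: Iterable[str] = ()
) -> pd.DataFrame:
    """Rank features by descending mean abundance across samples.

    Returns a table with columns ``rank``, ``feature_id``,
    ``mean_abundance``, ``highlighted`` (flag for the requested ids,
    e.g. curated gluten accessions).  Ties are broken by feature id.
    """
    if matrix.empty:
        raise ValueError("empty abundance matrix")
    highlight = set(highlight)
    means = matrix.mean(axis=1, skipna=True)
    order = sorted(means.index, key=lambda f: (-(means[f] if pd.notna(means[f]) else -np.inf), str(f)))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "feature_id": order,
            "mean_abundance": [means[f] for f in order],
            "highlighted": [f in highlight for f in order],
        }
    )
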