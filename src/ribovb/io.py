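"""Reading and writing the package's tab-separated file formats.

Counts travel as a wide TSV (first column ``gene_id``, one column per
observation) plus a metadata TSV with columns ``column_id``,
``sample_id``, ``condition``, ``preparation`` mapping every count
column to its sample and preparation.  A converter accepts the common
three-row-header dialect (treatment / sample / preparation header
lines).  Results are a TSV plus a JSON sidecar holding everything
needed to re-execute the run.
"""

from __future__ import annotations

import json

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, FormatError
from .fdr import FdrResult
from .model import PREPARATIONS, PairedCountTable
from .simulate import SimulatedDataset
from .vi import FitResult

METADATA_COLUMNS = ("column_id", "sample_id", "condition", "preparation")


def read_counts(
    counts_path: str | Path,
    metadata_path: str | Path,
    reference: str | None = None,
) -> PairedCountTable:
    """Load and validate a paired count table from two TSV files."""
    counts = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if counts.shape[1] < 2:
        raise FormatError("counts file needs gene ids plus count columns")
    gene_col = counts.columns[0]
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"metadata lacks columns: {sorted(missing)}")
    col_ids = list(counts.columns[1:])
    meta = meta.set_index("column_id")
    unmapped = [c for c in col_ids if c not in meta.index]
    if unmapped:
        raise FormatError(f"count columns not in metadata: {unmapped}")
    for col in col_ids:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"non-numeric count in column {col!r}")
        if (vals < 0).any():
            raise FormatError(f"negative count in column {col!r}")
        if (vals != np.floor(vals)).any():
            raise FormatError(f"non-integer count in column {col!r}")
    gene_ids = counts[gene_col].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError("duplicate gene id in counts file")
    col_sample = [meta.loc[c, "sample_id"] for c in col_ids]
    col_prep = [meta.loc[c, "preparation"] for c in col_ids]
    for c, p in zip(col_ids, col_prep):
        if p not in PREPARATIONS:
            raise FormatError(
                f"column {c!r}: preparation must be one of {PREPARATIONS}"
            )
    sample_ids = list(dict.fromkeys(col_sample))
    condition = {}
    for c, s in zip(col_ids, col_sample):
        cond = meta.loc[c, "condition"]
        if condition.setdefault(s, cond) != cond:
            raise FormatError(f"sample {s!r} has conflicting conditions")
    return PairedCountTable(
        gene_ids=gene_ids,
        counts=counts[col_ids].to_numpy(dtype=np.int64),
        sample_ids=sample_ids,
        condition=condition,
        col_sample=col_sample,
        col_prep=col_prep,
        reference=reference,
    )


def write_counts(
    table: PairedCountTable,
    counts_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a count table and its metadata as TSVs (read_counts inverse)."""
    col_ids = [f"{s}_{p}" for s, p in zip(table.col_sample, table.col_prep)]
    df = pd.DataFrame(table.counts, columns=col_ids)
    df.insert(0, "gene_id", table.gene_ids)
    df.to_csv(counts_path, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "column_id": col_ids,
            "sample_id": table.col_sample,
            "condition": [table.condition[s] for s in table.col_sample],
            "preparation": table.col_prep,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_counts_three_row_header(
    path: str | Path,
    control_label: str,
    reference: str | None = None,
) -> PairedCountTable:
    """Convert the three-row-header dialect (treatment / sample /
    preparation header lines over a gene-by-observation grid) into a
    validated :class:`PairedCountTable`.

    ``control_label`` names the treatment-row label to use as the
    reference condition when ``reference`` is not given.
    """
    raw = pd.read_csv(path, sep="\t", header=[0, 1, 2], index_col=0)
    conditions, samples, preps = zip(*raw.columns)

    def _ffill(labels: tuple[str, ...]) -> list[str]:
        out, last = [], None
        for lab in labels:
            if lab is None or str(lab).startswith("Unnamed"):
                lab = last
            out.append(str(lab))
            last = lab
        return out

    conditions = _ffill(conditions)
    samples = _ffill(samples)
    col_sample = [f"{c}:{s}" for c, s in zip(conditions, samples)]
    condition = dict(zip(col_sample, conditions))
    sample_ids = list(dict.fromkeys(col_sample))
    return PairedCountTable(
        gene_ids=[str(g) for g in raw.index],
        counts=raw.to_numpy(dtype=np.int64),
        sample_ids=sample_ids,
        condition=condition,
        col_sample=col_sample,
        col_prep=[str(p) for p in preps],
        reference=reference or control_label,
    )


def filter_low_counts(
    table: PairedCountTable, max_zero_fraction: float = 0.5
) -> tuple[PairedCountTable, list[str]]:
    """Drop genes whose fraction of zero cells exceeds the threshold.

    A gene is removed when strictly more than ``max_zero_fraction`` of
    its 2N count cells are zero.  Returns the filtered table and the
    removed gene ids; removing every gene is fatal.
    """
    if not 0 <= max_zero_fraction <= 1:
        raise ConfigurationError("max_zero_fraction must be in [0, 1]")
    zero_frac = (table.counts == 0).mean(axis=1)
    keep = np.nonzero(zero_frac <= max_zero_fraction)[0]
    removed = [table.gene_ids[g] for g in np.nonzero(zero_frac > max_zero_fraction)[0]]
    if keep.size == 0:
        raise FormatError(
            "zero-count filter removed every gene; lower max_zero_fraction"
        )
    return table.subset_genes(keep), removed


def write_results(
    fit: FitResult,
    fdr: FdrResult,
    path: str | Path,
    config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    """Write the per-gene results TSV and its JSON sidecar.

    The TSV reports the posterior null probability, its complement, the
    interaction effect on the natural-log model scale and on the log2
    reporting scale (conversion factor ln 2), and the FDR decision.
    The sidecar records config, seed, ELBO trace, convergence flag and
    software version, enough to re-execute the run.
    """
    path = Path(path)
    if fdr.null_probs.shape[0] != len(fit.gene_ids):
        raise ConfigurationError("fit and fdr results are inconsistent")
    df = pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "posterior_null_prob": fit.null_prob,
            "posterior_prob_dtg": 1.0 - fit.null_prob,
            "beta3_natural_log": fit.beta3_mean,
            "te_change_log2": fit.te_change_log2,
            "fdr_reject": fdr.reject.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "alpha": fdr.alpha,
        "threshold": fdr.threshold,
        "fdr_hat": fdr.fdr_hat,
        "min_abs_log2_te_change": fdr.min_abs_log2_te_change,
        "n_rejected": fdr.n_rejected,
        "converged": bool(fit.converged),
        "n_iterations": int(fit.n_iterations),
        "elbo_trace": [float(v) for v in fit.elbo_trace],
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_simulated_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write counts.tsv, metadata.tsv and truth.tsv for a simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(dataset.table, out / "counts.tsv", out / "metadata.tsv")
    truth = pd.DataFrame(
        {
            "gene_id": dataset.table.gene_ids,
            "beta0": [t.beta[0] for t in dataset.truth],
            "beta1": [t.beta[1] for t in dataset.truth],
            "beta2": [t.beta[2] for t in dataset.truth],
            "beta3": [t.beta[3] for t in dataset.truth],
            "is_dtg": dataset.is_dtg.astype(int),
        }
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
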