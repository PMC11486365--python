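"""The three analysis scenarios and their CSV artifacts.

``run_single`` writes per-residue angle tables, circular statistics and
angular histograms for one structure.  ``run_vs_target`` compares up to ten
models against a target (per-residue MCQ + severity, coverage percentages,
LCS-TA segments, per-angle differences).  ``run_vs_models`` builds the
all-pairs MCQ dissimilarity matrix and its MDS embedding, k-medoids
clustering and UPGMA dendrogram.

CSV conventions: RFC-4180, "." decimal separator, angles to two decimals in
(−180°, 180°] (pseudorotation phase in [0°, 360°)), blank cells for
undefined values.  Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import angle_stats, comparison, ensemble
from .comparison import DEFAULT_ANGLES
from .errors import ConfigError, SelectionError
from .model import NucleicChain, Selection
from .structure_io import parse_structure, select
from .torsion_core import AngleKind, ResidueTorsions, chain_torsions

__all__ = ["RunConfig", "run_single", "run_vs_target", "run_vs_models"]

MAX_VS_TARGET_MODELS = 10

_ANGLE_COLUMNS = [
    AngleKind.alpha, AngleKind.beta, AngleKind.gamma, AngleKind.delta,
    AngleKind.epsilon, AngleKind.zeta, AngleKind.chi,
    AngleKind.nu0, AngleKind.nu1, AngleKind.nu2, AngleKind.nu3, AngleKind.nu4,
    AngleKind.pseudorotation,
    AngleKind.eta, AngleKind.theta, AngleKind.eta_prime, AngleKind.theta_prime,
]


@dataclass
class RunConfig:
    """Shared configuration of the three scenarios."""

    inputs: list[Path]
    output_dir: Path
    model_number: int = 1
    chain_ids: Optional[list[str]] = None
    auth_range: Optional[tuple[int, int]] = None  # 1-based inclusive author numbers
    angles: tuple[AngleKind, ...] = DEFAULT_ANGLES
    lcs_threshold: float = 15.0
    k: Optional[int] = None
    seed: int = 0
    plots: bool = False


def _read_chains(path: Path, cfg: RunConfig) -> list[NucleicChain]:
    text = Path(path).read_text()
    models = parse_structure(text)
    numbers = [m.model_number for m in models]
    number = cfg.model_number if cfg.model_number in numbers else numbers[0]
    sel = Selection(model_number=number, chain_ids=cfg.chain_ids, residue_range=None)
    chains = select(models, sel)
    if cfg.auth_range is None:
        return chains
    lo, hi = cfg.auth_range
    out = []
    for chain in chains:
        positions = [
            i for i, r in enumerate(chain.residues) if lo <= r.auth_number <= hi
        ]
        if not positions:
            raise SelectionError(
                f"no residue of chain {chain.chain_id!r} has an author number "
                f"in [{lo}, {hi}]"
            )
        span = Selection(
            model_number=number,
            chain_ids=[chain.chain_id],
            residue_range=(positions[0], positions[-1] + 1),
        )
        out.extend(select(models, span))
    return out


def _fmt(x: float) -> str:
    return "" if x is None or not np.isfinite(x) else f"{x:.2f}"


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _torsion_rows(chain: NucleicChain, torsions: Sequence[ResidueTorsions]):
    for res, t in zip(chain.residues, torsions):
        row = {
            "chain": res.chain_id,
            "auth_number": res.auth_number,
            "ins_code": res.insertion_code,
            "name": res.name,
        }
        for kind in _ANGLE_COLUMNS:
            row[kind.value] = _fmt(t.get(kind))
        row["pucker"] = t.pucker or ""
        row["glycosidic"] = "" if t.glycosidic == "undefined" else t.glycosidic
        yield row


def run_single(cfg: RunConfig) -> dict[str, Path]:
    """Single-model scenario → torsions.csv, statistics.csv, histograms.csv."""
    if len(cfg.inputs) != 1:
        raise ConfigError("the single scenario takes exactly one structure file")
    chains = _read_chains(cfg.inputs[0], cfg)
    per_chain = [(c, chain_torsions(c)) for c in chains]
    out = Path(cfg.output_dir)

    torsion_df = pd.DataFrame(
        [row for chain, torsions in per_chain for row in _torsion_rows(chain, torsions)]
    )
    paths = {"torsions": _write_csv(torsion_df, out / "torsions.csv")}

    all_torsions = [t for _, ts in per_chain for t in ts]
    stat_rows = []
    for kind in _ANGLE_COLUMNS:
        summary = angle_stats.circular_mean([t.get(kind) for t in all_torsions], kind)
        stat_rows.append(
            {
                "name": kind.value,
                "n": summary.n_defined,
                "circular_mean": _fmt(summary.mean),
                "resultant_length": (
                    "" if not np.isfinite(summary.resultant_length)
                    else f"{summary.resultant_length:.4f}"
                ),
                "circular_std": _fmt(summary.circular_std),
            }
        )
    counts = angle_stats.syn_anti_counts(all_torsions)
    for key in ("syn", "anti", "undefined"):
        stat_rows.append(
            {"name": f"glycosidic_{key}", "n": counts[key],
             "circular_mean": "", "resultant_length": "", "circular_std": ""}
        )
    paths["statistics"] = _write_csv(pd.DataFrame(stat_rows), out / "statistics.csv")

    hist_rows = []
    for kind in _ANGLE_COLUMNS:
        lo = 0.0 if kind is AngleKind.pseudorotation else -180.0
        hist = angle_stats.histogram(
            [t.get(kind) for t in all_torsions], bin_width=15.0, lo=lo, kind=kind
        )
        edges = hist.edges
        for b, count in enumerate(hist.counts):
            hist_rows.append(
                {"name": kind.value, "bin_start": f"{edges[b]:.1f}",
                 "bin_end": f"{edges[b + 1]:.1f}", "count": int(count)}
            )
    paths["histograms"] = _write_csv(pd.DataFrame(hist_rows), out / "histograms.csv")

    if cfg.plots:
        paths["histograms_svg"] = _plot_histograms(all_torsions, out / "histograms.svg")
    return paths


def _plot_histograms(torsions, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(5, 4, figsize=(14, 12))
    for ax, kind in zip(axes.flat, _ANGLE_COLUMNS):
        lo = 0.0 if kind is AngleKind.pseudorotation else -180.0
        hist = angle_stats.histogram(
            [t.get(kind) for t in torsions], bin_width=15.0, lo=lo, kind=kind
        )
        ax.bar(hist.edges[:-1], hist.counts, width=hist.bin_width, align="edge")
        ax.set_title(kind.symbol)
    for ax in axes.flat[len(_ANGLE_COLUMNS):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def _labels_for(paths: Sequence[Path]) -> list[str]:
    labels = []
    for p in paths:
        stem = Path(p).stem
        label = stem
        i = 2
        while label in labels:
            label = f"{stem}_{i}"
            i += 1
        labels.append(label)
    return labels


def run_vs_target(cfg: RunConfig) -> dict[str, Path]:
    """Model(s)-vs-target scenario.

    The first input is the target, the rest (1–10) are models.  The first
    selected chain of each structure is compared.
    """
    if len(cfg.inputs) < 2:
        raise ConfigError("vs-target needs a target plus at least one model")
    n_models = len(cfg.inputs) - 1
    if n_models > MAX_VS_TARGET_MODELS:
        raise ConfigError(
            f"vs-target accepts at most {MAX_VS_TARGET_MODELS} models per run; "
            f"got {n_models}"
        )
    out = Path(cfg.output_dir)
    target_chain = _read_chains(cfg.inputs[0], cfg)[0]
    target_t = chain_torsions(target_chain)
    labels = _labels_for(cfg.inputs[1:])

    per_res_rows, glob_rows, cov_rows, lcs_rows = [], [], [], []
    paths: dict[str, Path] = {}
    for path, label in zip(cfg.inputs[1:], labels):
        model_cfg = RunConfig(
            inputs=[path], output_dir=cfg.output_dir,
            model_number=cfg.model_number, chain_ids=None, auth_range=None,
        )
        model_chain = _read_chains(path, model_cfg)[0]
        model_t = chain_torsions(model_chain)
        pairing = comparison.pair_residues(target_chain.sequence, model_chain.sequence)

        rows = comparison.per_residue_mcq(target_t, model_t, pairing, cfg.angles)
        for r in rows:
            res = target_chain.residues[r.target_position]
            per_res_rows.append(
                {
                    "model": label,
                    "chain": res.chain_id,
                    "auth_number": res.auth_number,
                    "ins_code": res.insertion_code,
                    "mcq": _fmt(r.mcq.degrees),
                    "severity": r.severity or "",
                }
            )
        g = comparison.global_mcq(target_t, model_t, pairing, cfg.angles)
        glob_rows.append(
            {"model": label, "mcq": _fmt(g.degrees), "n_terms": g.n_terms,
             "paired_residues": len(pairing)}
        )
        fracs, n_def = comparison.coverage_fractions(rows)
        cov_rows.append(
            {
                "model": label,
                "pct_below_15": _fmt(fracs[0] * 100 if np.isfinite(fracs[0]) else float("nan")),
                "pct_below_30": _fmt(fracs[1] * 100 if np.isfinite(fracs[1]) else float("nan")),
                "pct_below_60": _fmt(fracs[2] * 100 if np.isfinite(fracs[2]) else float("nan")),
                "n_defined": n_def,
            }
        )
        seg = comparison.lcs_ta(target_t, model_t, pairing, cfg.angles, cfg.lcs_threshold)
        lcs_rows.append(
            {
                "model": label,
                "target_start": (
                    "" if seg.target_start is None
                    else target_chain.residues[seg.target_start].auth_number
                ),
                "model_start": (
                    "" if seg.model_start is None
                    else model_chain.residues[seg.model_start].auth_number
                ),
                "length": seg.length,
                "mcq": _fmt(seg.mcq.degrees),
            }
        )
        diff_rows = []
        for ti, mi in pairing:
            res = target_chain.residues[ti]
            row = {"chain": res.chain_id, "auth_number": res.auth_number,
                   "model_auth_number": model_chain.residues[mi].auth_number}
            for kind in cfg.angles:
                d = comparison.angle_diff(target_t[ti].get(kind), model_t[mi].get(kind))
                row[f"delta_{kind.value}"] = _fmt(d.delta)
            diff_rows.append(row)
        paths[f"differences_{label}"] = _write_csv(
            pd.DataFrame(diff_rows), out / f"differences_{label}.csv"
        )

    paths["per_residue_mcq"] = _write_csv(pd.DataFrame(per_res_rows), out / "per_residue_mcq.csv")
    paths["global"] = _write_csv(pd.DataFrame(glob_rows), out / "global.csv")
    paths["coverage"] = _write_csv(pd.DataFrame(cov_rows), out / "coverage.csv")
    paths["lcs_ta"] = _write_csv(pd.DataFrame(lcs_rows), out / "lcs_ta.csv")
    return paths


def run_vs_models(cfg: RunConfig) -> dict[str, Path]:
    """Model-vs-model scenario → dissimilarity matrix, MDS, clusters, dendrogram."""
    if len(cfg.inputs) < 2:
        raise ConfigError("vs-models needs at least two model files")
    if cfg.k is None:
        raise ConfigError("vs-models requires an explicit cluster count k")
    out = Path(cfg.output_dir)
    labels = _labels_for(cfg.inputs)
    chains = []
    for path in cfg.inputs:
        single = RunConfig(inputs=[path], output_dir=cfg.output_dir,
                           model_number=cfg.model_number)
        chains.append(_read_chains(path, single)[0])

    matrix = ensemble.dissimilarity_matrix(chains, cfg.angles, labels)
    mat_df = pd.DataFrame(
        [[label] + [_fmt(v) for v in row] for label, row in zip(labels, matrix.values)],
        columns=["model"] + labels,
    )
    paths = {"dissimilarity": _write_csv(mat_df, out / "dissimilarity.csv")}

    emb = ensemble.classical_mds(matrix, dims=2)
    mds_df = pd.DataFrame(
        {
            "model": emb.labels,
            "x": [f"{v:.4f}" for v in emb.coords[:, 0]],
            "y": [f"{v:.4f}" for v in emb.coords[:, 1]],
        }
    )
    paths["mds"] = _write_csv(mds_df, out / "mds.csv")

    clusters = ensemble.k_medoids(matrix, cfg.k, seed=cfg.seed)
    cl_df = pd.DataFrame(
        {
            "model": clusters.labels,
            "cluster": clusters.assignment,
            "is_medoid": [
                int(i in clusters.medoid_indices) for i in range(matrix.n)
            ],
        }
    )
    paths["clusters"] = _write_csv(cl_df, out / "clusters.csv")

    tree = ensemble.dendrogram(matrix)
    newick_path = out / "dendrogram.newick"
    newick_path.parent.mkdir(parents=True, exist_ok=True)
    newick_path.write_text(tree.to_newick() + "\n")
    paths["dendrogram"] = newick_path
    return paths
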