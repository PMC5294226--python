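"""Side-by-side comparison of elastic-network and contact-network results.

The two frameworks look at the same structure through different lenses:
the ENM side produces mean-square fluctuations, hinge sites, hot spots
and commute-time minima; the PCN side produces centralities and the
Guimerà–Amaral cartography. This module aligns all per-residue columns
on the shared residue index, computes the Pearson correlation grid
(closeness/MF, betweenness/MF, P/MF, P/CT), and cross-tabulates the
key-residue sets with Jaccard indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .structures import CoarseStructure

__all__ = ["ComparisonReport", "pearson", "jaccard", "build_report"]


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant column."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation with pairwise deletion of missing values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("columns must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def jaccard(a: Sequence[int], b: Sequence[int]) -> float:
    """Jaccard index |A∩B| / |A∪B| of two residue-position sets."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass
class ComparisonReport:
    """Aligned per-residue table, correlation grid and set concordance."""

    table: pd.DataFrame  # per-residue: index, chain, resnum, resname + value columns
    correlations: dict[str, float]  # e.g. "closeness/MF" -> r
    concordance: dict[str, dict[str, float | list[int]]]

    def to_files(self, outdir: str | Path, prefix: str = "report") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / f"{prefix}_residues.tsv", sep="\t", index=False,
                          float_format="%.12g")
        grid = pd.DataFrame([self.correlations])
        grid.to_csv(outdir / f"{prefix}_correlations.tsv", sep="\t", index=False,
                    float_format="%.6f")
        (outdir / f"{prefix}_concordance.json").write_text(
            json.dumps(self.concordance, indent=2, sort_keys=True) + "\n"
        )


def build_report(
    structure: CoarseStructure,
    mean_fluctuations: np.ndarray,
    average_commute: np.ndarray,
    degree: np.ndarray,
    betweenness: np.ndarray,
    closeness: np.ndarray,
    participation: np.ndarray,
    z_score: np.ndarray,
    key_sets: Mapping[str, Sequence[int]] | None = None,
) -> ComparisonReport:
    """Assemble the comparison layer for one structure.

    All arrays must be index-aligned per-residue columns of length N.
    ``key_sets`` maps set names (e.g. hinges, hotspots, commute_minima,
    R4, R5) to 0-based residue positions; every pair of sets gets a
    Jaccard index.
    """
    n = len(structure)
    columns = {
        "MF": mean_fluctuations,
        "CT": average_commute,
        "degree": degree,
        "betweenness": betweenness,
        "closeness": closeness,
        "P": participation,
        "z": z_score,
    }
    for name, col in columns.items():
        if np.asarray(col).shape[0] != n:
            raise ValueError(f"column {name!r} has wrong length (expected {n})")
    table = pd.DataFrame(
        {
            "index": structure.index,
            "chain": [r.chain for r in structure.residues],
            "resnum": [r.seqnum for r in structure.residues],
            "resname": [r.name for r in structure.residues],
            **{k: np.asarray(v, float) for k, v in columns.items()},
        }
    )
    correlations = {
        "closeness/MF": pearson(closeness, mean_fluctuations),
        "betweenness/MF": pearson(betweenness, mean_fluctuations),
        "P/MF": pearson(participation, mean_fluctuations),
        "P/CT": pearson(participation, average_commute),
    }
    concordance: dict[str, dict[str, float | list[int]]] = {}
    if key_sets:
        names = sorted(key_sets)
        for name in names:
            concordance[name] = {"residues": sorted(int(i) for i in key_sets[name])}
        for i, na in enumerate(names):
            for nb in names[i + 1 :]:
                concordance[f"{na}|{nb}"] = {
                    "jaccard": jaccard(key_sets[na], key_sets[nb])
                }
    return ComparisonReport(table=table, correlations=correlations, concordance=concordance)


def analyze_structure(
    structure: CoarseStructure,
    gnm_cutoff: float = 7.0,
    atom_cutoff: float = 4.0,
    window: tuple[float, float] = (4.0, 8.0),
    iterations: int = 2,
    largest_component: bool = False,
) -> ComparisonReport:
    """Run the full two-framework analysis on one structure.

    Mean fluctuations are the all-nonzero-mode GNM profile (the default
    flexibility measure of the comparison grid); the commute-time
    column uses the affinity-Laplacian Markov model; the PCN side uses
    the 4–8 Å window with two rounds of spectral bisection.
    """
    from . import elastic, markov, pcn

    params = elastic.ElasticParams(gnm_cutoff=gnm_cutoff)
    modes = elastic.decompose(elastic.build_kirchhoff(structure, params), params)
    msf = elastic.square_fluctuations(modes)
    hinges = elastic.hinge_sites(structure, elastic.mode_shape(modes, 1))

    aff = markov.affinity_matrix(structure, atom_cutoff=atom_cutoff)
    cmap = markov.hitting_times(aff)
    minima = markov.allosteric_minima(cmap, structure)

    net = pcn.build_pcn(structure, window=window)
    desc = pcn.descriptors(net, largest_component=largest_component)
    part = pcn.spectral_clustering(net, iterations=iterations)
    carto = pcn.cartography(net, part)
    key_sets = {
        "hinges": hinges,
        "commute_minima": minima,
        "R4": [i for i, r in enumerate(carto.regions) if r == "R4"],
        "R5": [i for i, r in enumerate(carto.regions) if r == "R5"],
    }
    return build_report(
        structure,
        mean_fluctuations=msf,
        average_commute=cmap.average_commute,
        degree=desc.degree,
        betweenness=desc.betweenness,
        closeness=desc.closeness,
        participation=carto.participation,
        z_score=carto.z_score,
        key_sets=key_sets,
    )
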