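"""Synthetic CFG-style glycan-array data with planted community structure.

Real glycan-array collections are per-lectin result files over a shared
glycan panel where the vast majority of spots are low-RFU background: in the
collection this generator emulates only about 3.5% of all spots exceed RFU
5000.  The generator plants:

* ``n_communities`` lectin communities, each with its own block of panel
  glycans; a lectin gets a super-cutoff RFU on a glycan of its own block with
  probability ``p_in`` and on another block's glycan with probability
  ``p_out``;
* a pool of background-only panel glycans that never receive super-cutoff
  signal (real panels are much wider than any one lectin's binding profile --
  without them no parameter choice can push the super-cutoff fraction down
  to a few percent);
* a handful of hub lectins with near-certain binding across all blocks,
  giving the degree distribution a recoverable top-degree gap;
* per-lectin specificity labels: with probability ``purity`` the community's
  dominant label, otherwise a uniform draw from the label pool.

Super-cutoff RFUs are log-normal truncated to >= cutoff and background RFUs
log-normal truncated to < cutoff, reproducing the long right tail of real RFU
histograms with no leakage across the cutoff.  ``background_fill`` (the
probability that a non-signal spot is printed at all) is calibrated in closed
form so the expected super-cutoff fraction of printed rows matches
``target_super_fraction``.  Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import stats

from .array_io import ArrayExperiment, InteractionTable, merge_experiments
from .enrichment import AnnotationMap

__all__ = [
    "PlantedConfig",
    "PlantedTruth",
    "generate_planted_dataset",
    "expected_edge_count",
    "write_dataset",
]

DEFAULT_LABEL_POOL = [
    "Mannose binding lectin",
    "Galb1-3GalNAc",
    "Chitin oligomers, Sia",
    "Fucose binding lectin",
    "a-Linked terminal GalNAc",
    "Siaa2-6Gal/GalNAc",
    "Galb1-4GlcNAc",
    "High-mannose, Mana1-3Man",
]

# determinant embedded in each community's glycan structures, aligned with
# the community's dominant specificity label
DEFAULT_DETERMINANTS = [
    "Mana1-6(Mana1-3)Man",
    "Galb1-3GalNAc",
    "GlcNAcb1-4GlcNAc",
    "Fuca1-2Gal",
    "GalNAca1-3Gal",
    "Neu5Aca2-6Gal",
    "Galb1-4GlcNAc",
    "Mana1-3Man",
]

_FILLER = ["Galb1-4Glc", "GlcNAcb1-3Gal", "Mana1-2Man", "Galb1-3GlcNAc"]


@dataclass
class PlantedConfig:
    """Study conditions of the synthetic glycan-array collection."""

    n_communities: int = 4
    proteins_per_community: int = 30
    glycans_per_community: int = 40
    p_in: float = 0.3
    p_out: float = 0.02
    rfu_cutoff: float = 5000.0
    mu_sig: float = math.log(12000.0)
    sigma_sig: float = 0.6
    mu_bg: float = math.log(300.0)
    sigma_bg: float = 1.0
    background_glycans: int = 360
    background_fill: Optional[float] = None  # None -> calibrated
    target_super_fraction: float = 0.035
    n_hubs: int = 3
    p_hub_home: float = 0.95
    p_hub_away: float = 0.80
    label_pool: list[str] = field(default_factory=lambda: list(DEFAULT_LABEL_POOL))
    purity: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not (0 <= self.purity <= 1):
            raise ValueError("purity must be in [0, 1]")
        if self.mu_sig <= self.mu_bg:
            raise ValueError("signal RFU law must sit above the background law")
        if len(self.label_pool) < self.n_communities:
            raise ValueError("label pool smaller than the number of communities")


@dataclass
class PlantedTruth:
    """Ground truth serialized alongside the generated files."""

    community_of: dict[str, int]
    dominant_label: dict[int, str]
    labels_of: dict[str, str]
    n_edges: int
    hub_ids: list[str]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "community_of": self.community_of,
            "dominant_label": {str(k): v for k, v in self.dominant_label.items()},
            "labels_of": self.labels_of,
            "n_edges": self.n_edges,
            "hub_ids": self.hub_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def expected_edge_count(config: PlantedConfig) -> float:
    """Closed-form expected number of super-cutoff (filtered-network) edges.

    Planted block: Nc*P*G*p_in + Nc*(Nc-1)*P*G*p_out; hub lectins add
    n_hubs * G * (p_hub_home + (Nc-1)*p_hub_away).
    """
    config.validate()
    nc, p, g = config.n_communities, config.proteins_per_community, config.glycans_per_community
    planted = nc * p * g * config.p_in + nc * (nc - 1) * p * g * config.p_out
    hubs = config.n_hubs * g * (config.p_hub_home + (nc - 1) * config.p_hub_away)
    return planted + hubs


def _calibrated_background_fill(config: PlantedConfig) -> float:
    """Solve for the fill making E[super rows]/E[all rows] hit the target."""
    nc, g = config.n_communities, config.glycans_per_community
    panel = nc * g + config.background_glycans
    n_planted = nc * config.proteins_per_community
    e_super = expected_edge_count(config)
    e_sig_planted = g * config.p_in + (nc - 1) * g * config.p_out
    e_sig_hub = g * (config.p_hub_home + (nc - 1) * config.p_hub_away)
    # non-signal spots available per protein, times fill, gives background rows
    e_bg_capacity = (n_planted * (panel - e_sig_planted)
                     + config.n_hubs * (panel - e_sig_hub))
    f = config.target_super_fraction
    needed_bg = e_super * (1.0 - f) / f
    fill = needed_bg / e_bg_capacity
    return float(min(max(fill, 0.0), 1.0))


def _trunc_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                     size: int, lower: Optional[float] = None,
                     upper: Optional[float] = None) -> np.ndarray:
    """Log-normal samples truncated to [lower, upper) by inverse CDF."""
    lo = 0.0 if lower is None else stats.norm.cdf((math.log(lower) - mu) / sigma)
    hi = 1.0 if upper is None else stats.norm.cdf((math.log(upper) - mu) / sigma)
    u = rng.uniform(lo, hi, size=size)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _glycan_structure(rng: np.random.Generator, determinant: str) -> str:
    """A small IUPAC-condensed-looking string embedding the determinant."""
    prefix = _FILLER[rng.integers(len(_FILLER))]
    link = f"b1-{rng.integers(2, 7)}"
    spacer = f"-Sp{rng.integers(0, 26)}"
    if rng.random() < 0.5:
        return f"{determinant}{link}{prefix}{spacer}"
    return f"{prefix}{link}{determinant}{spacer}"


def generate_planted_dataset(
        config: Optional[PlantedConfig] = None,
) -> tuple[list[ArrayExperiment], AnnotationMap, PlantedTruth]:
    """Generate per-lectin array experiments with planted ground truth.

    Returns in-memory experiments (use :func:`write_dataset` to emit the TSV
    files), the specificity annotation map, and the planted truth.  Byte-for-
    byte deterministic given ``config.seed``.
    """
    config = config or PlantedConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    fill = (config.background_fill if config.background_fill is not None
            else _calibrated_background_fill(config))

    nc, ppc, gpc = (config.n_communities, config.proteins_per_community,
                    config.glycans_per_community)

    # panel: community blocks then background-only glycans
    glycan_ids: list[str] = []
    glycan_struct: dict[str, str] = {}
    glycan_comm: dict[str, int] = {}
    for c in range(nc):
        det = DEFAULT_DETERMINANTS[c % len(DEFAULT_DETERMINANTS)]
        for j in range(gpc):
            gid = f"G{c}_{j:03d}"
            glycan_ids.append(gid)
            glycan_struct[gid] = _glycan_structure(rng, det)
            glycan_comm[gid] = c
    for j in range(config.background_glycans):
        gid = f"GB_{j:03d}"
        glycan_ids.append(gid)
        glycan_struct[gid] = _glycan_structure(rng, _FILLER[j % len(_FILLER)])

    proteins: list[tuple[str, str, int, bool]] = []  # (node_id, name, comm, is_hub)
    for c in range(nc):
        for i in range(ppc):
            node = f"100{c}{i:03d}"
            proteins.append((node, f"lectin_{c}_{i:02d}", c, False))
    for h in range(config.n_hubs):
        node = f"1099{h:03d}"
        proteins.append((node, f"hub_lectin_{h}", h % nc, True))

    community_of: dict[str, int] = dict(glycan_comm)
    labels_of: dict[str, str] = {}
    dominant = {c: config.label_pool[c] for c in range(nc)}
    experiments: list[ArrayExperiment] = []
    n_edges = 0

    import pandas as pd

    for node, name, comm, is_hub in proteins:
        community_of[node] = comm
        # planted specificity label
        if rng.random() < config.purity:
            labels_of[name] = dominant[comm]
        else:
            labels_of[name] = config.label_pool[rng.integers(len(config.label_pool))]

        rows_id, rows_struct, rows_rfu = [], [], []
        draws = rng.random(len(glycan_ids))
        sig_flags = np.zeros(len(glycan_ids), dtype=bool)
        for idx, gid in enumerate(glycan_ids):
            gc = glycan_comm.get(gid)
            if gc is None:
                p_edge = 0.0
            elif is_hub:
                p_edge = config.p_hub_home if gc == comm else config.p_hub_away
            else:
                p_edge = config.p_in if gc == comm else config.p_out
            sig_flags[idx] = draws[idx] < p_edge
        bg_flags = (~sig_flags) & (rng.random(len(glycan_ids)) < fill)

        n_sig = int(sig_flags.sum())
        n_bg = int(bg_flags.sum())
        sig_rfu = _trunc_lognormal(rng, config.mu_sig, config.sigma_sig,
                                   n_sig, lower=config.rfu_cutoff)
        bg_rfu = _trunc_lognormal(rng, config.mu_bg, config.sigma_bg,
                                  n_bg, upper=config.rfu_cutoff)
        si = bi = 0
        for idx, gid in enumerate(glycan_ids):
            if sig_flags[idx]:
                rfu = round(float(sig_rfu[si]), 2); si += 1
            elif bg_flags[idx]:
                rfu = round(float(bg_rfu[bi]), 2); bi += 1
                if rfu >= config.rfu_cutoff:  # rounding must not cross the cutoff
                    rfu = config.rfu_cutoff - 0.01
            else:
                continue
            rows_id.append(gid)
            rows_struct.append(glycan_struct[gid])
            rows_rfu.append(rfu)
        n_edges += n_sig

        experiments.append(ArrayExperiment(
            lectin_node_id=node, protein_name=name,
            condition="synthetic planted assay",
            rows=pd.DataFrame({"glycan_id": rows_id,
                               "glycan_structure": rows_struct,
                               "rfu": rows_rfu})))

    ann = AnnotationMap(
        labels={name: {lab} for name, lab in labels_of.items()},
        node_map={node: name for node, name, _, _ in proteins})
    truth = PlantedTruth(
        community_of=community_of,
        dominant_label=dominant,
        labels_of=labels_of,
        n_edges=n_edges,
        hub_ids=[node for node, _, _, is_hub in proteins if is_hub])
    return experiments, ann, truth


def write_dataset(experiments: list[ArrayExperiment], ann: AnnotationMap,
                  truth: PlantedTruth, out_dir: Union[str, Path]) -> Path:
    """Emit array TSVs, the annotation TSV and the truth sidecar."""
    out = Path(out_dir)
    (out / "arrays").mkdir(parents=True, exist_ok=True)
    for exp in experiments:
        path = out / "arrays" / f"{exp.lectin_node_id}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#lectin_node_id\t{exp.lectin_node_id}\n")
            fh.write(f"#protein_name\t{exp.protein_name}\n")
            fh.write(f"#condition\t{exp.condition}\n")
            fh.write("glycan_id\tglycan_structure\trfu\n")
            for gid, struct, rfu in exp.rows.itertuples(index=False):
                fh.write(f"{gid}\t{struct}\t{rfu:.2f}\n")
    with open(out / "annotations.tsv", "w", encoding="utf-8") as fh:
        fh.write("protein_name\tspecificity\n")
        for name in sorted(ann.labels):
            for lab in sorted(ann.labels[name]):
                fh.write(f"{name}\t{lab}\n")
    with open(out / "node_map.tsv", "w", encoding="utf-8") as fh:
        fh.write("lectin_node_id\tprotein_name\n")
        for node in sorted(ann.node_map):
            fh.write(f"{node}\t{ann.node_map[node]}\n")
    truth.to_json(out / "truth.json")
    return out


def planted_interaction_table(config: Optional[PlantedConfig] = None):
    """Convenience: generate and merge in one step."""
    experiments, ann, truth = generate_planted_dataset(config)
    return merge_experiments(experiments), ann, truth
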