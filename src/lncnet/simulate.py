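"""Synthetic two-population, three-layer cohort generator with ground truth.

Emulates the statistical structure the cascade assumes: two sample groups
(default 75 vs 69), nuisance batch structure on the expression layers, planted
differentially expressed features at log2 effects 0.58–1.6, a co-expressed
lncRNA:mRNA hub block driven by a single latent factor (within-block Pearson
r ≈ 0.98), and a handful of microbial OTUs coupled to the same factor at
|r| ≈ 0.7.  A :class:`GroundTruthManifest` records every planted feature,
edge, and coupling so recovery can be tested end to end.

The hub is a latent single-factor model: per sample, h = μ·g + ε with
ε ~ N(0,1) and g the group indicator (μ defaults to 2 so the hub separates
the groups); the realized factor is standardized to unit sample variance so
that hub features x = h + N(0, σ²) with σ² = 1/r − 1 hit the target
within-block correlation in closed form.  Coupled OTU log2 abundances are
b·sign·h + noise with b solved from the coupling target; raw OTU tables are
produced by exponentiating and rounding to non-negative integer counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .types import GeneSetCollection, Layer, OmicsMatrix, SampleMetadata, Scale

__all__ = [
    "SyntheticConfig",
    "GroundTruthManifest",
    "CohortBundle",
    "generate_cohort",
    "write_fixture",
    "load_fixture",
    "small_fixture_config",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the cohort scale the cascade targets: 75 vs 69 samples,
    planted hub of 46 lncRNAs × 20 mRNAs at r = 0.98, 5 OTUs coupled at
    |r| = 0.7, and differential log2 effects drawn from [0.58, 1.6]
    (a 1.5- to 3-fold change).
    """

    n_group_a: int = 75          # reference group (default label RUS)
    n_group_b: int = 69          # comparison group (default label FIN)
    n_mrna: int = 2000
    n_lncrna: int = 1500
    n_otu: int = 200
    n_de_mrna: int = 300
    n_de_lncrna: int = 200
    n_de_otu: int = 40
    de_log2_effect_range: tuple[float, float] = (0.58, 1.6)
    n_hub_lncrna: int = 46
    n_hub_mrna: int = 20
    hub_target_r: float = 0.98
    n_coupled_otu: int = 5
    otu_coupling_r: float = 0.7
    hub_group_mu: float = 2.0    # latent-factor group separation
    batch_shift_sd: float = 0.5  # per-batch per-feature offset SD (log2 units)
    noise_sd: float = 1.0        # expression residual SD (log2 units)
    otu_noise_sd: float = 2.0    # OTU log2-abundance residual SD
    baseline_expr: float = 8.0   # mean log2 intensity
    baseline_otu: float = 7.0    # mean log2 abundance
    n_batches: int = 2           # levels of the single "labeling" batch factor
    n_pooled_extra: int = 53     # extra DE mRNAs in planted sets beyond the hub
    n_planted_sets: int = 7      # "response to bacterium" gene sets
    n_decoy_sets: int = 8
    n_disease_decoys: int = 481  # disease-list genes outside the pooled genes
    group_labels: tuple[str, str] = ("RUS", "FIN")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_mrna", "n_lncrna", "n_otu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hub_target_r < 1:
            raise ValueError("hub_target_r must be in (0, 1)")
        if not 0 < self.otu_coupling_r < 1:
            raise ValueError("otu_coupling_r must be in (0, 1)")
        if self.n_hub_mrna > self.n_de_mrna:
            raise ValueError("hub mRNA count exceeds planted DE mRNA count")
        if self.n_hub_lncrna > self.n_de_lncrna:
            raise ValueError("hub lncRNA count exceeds planted DE lncRNA count")
        if self.n_coupled_otu > self.n_de_otu:
            raise ValueError("coupled OTU count exceeds planted DE OTU count")
        lo, hi = self.de_log2_effect_range
        if not 0 <= lo <= hi:
            raise ValueError("de_log2_effect_range must be ordered and non-negative")
        if self.n_de_mrna > self.n_mrna or self.n_de_lncrna > self.n_lncrna \
                or self.n_de_otu > self.n_otu:
            raise ValueError("planted DE counts exceed layer feature counts")


@dataclass
class GroundTruthManifest:
    """Record of every planted effect, for recovery testing."""

    de_features: dict            # layer -> list of {feature_id, log2_effect, direction}
    hub_lncrna: list
    hub_mrna: list
    hub_edges: list              # (lncrna_id, mrna_id, target_r)
    coupled_otus: list           # (otu_id, sign)
    otu_couplings: list          # (lncrna_id, otu_id, sign)
    pooled_genes: list           # hub mRNAs + planted extras (the "73" analogue)
    disease_genes: list
    planted_set_names: list
    decoy_set_names: list

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruthManifest":
        return cls(**{k: obj[k] for k in cls.__dataclass_fields__})


@dataclass
class CohortBundle:
    mrna: OmicsMatrix
    lncrna: OmicsMatrix
    otu: OmicsMatrix
    metadata: SampleMetadata
    gene_sets: GeneSetCollection
    disease_genes: list
    manifest: GroundTruthManifest
    config: SyntheticConfig


def _planted_effects(rng, n, lo, hi):
    mag = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return mag * sign


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Draw a full three-layer cohort plus gene sets, disease list, and truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_group_a + cfg.n_group_b
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    g = np.concatenate([np.zeros(cfg.n_group_a), np.ones(cfg.n_group_b)])
    # centered group-A indicator: positive planted effects mean "up in group A"
    gc = (1.0 - g) - (1.0 - g).mean()

    # latent hub factor, elevated in group A, standardized to unit variance
    h_raw = cfg.hub_group_mu * (1.0 - g) + rng.normal(size=n)
    h_scale = h_raw.std(ddof=1)
    h = (h_raw - h_raw.mean()) / h_scale
    hub_effect = cfg.hub_group_mu / h_scale  # realized group diff of h

    sigma_hub = np.sqrt(1.0 / cfg.hub_target_r - 1.0)

    def expression_layer(prefix, n_feat, n_de, n_hub, baseline):
        ids = [f"{prefix}{i+1:06d}" for i in range(n_feat)]
        base = rng.normal(baseline, 2.0, size=n_feat)
        x = base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_feat, n))
        effects = np.zeros(n_feat)
        # hub block: first n_hub features ride the latent factor
        if n_hub:
            hub_noise = rng.normal(0.0, sigma_hub, size=(n_hub, n))
            x[:n_hub] = base[:n_hub, None] + h[None, :] + hub_noise
            effects[:n_hub] = hub_effect
        # remaining planted DE: additive group effect
        if n_de > n_hub:
            delta = _planted_effects(rng, n_de - n_hub, *cfg.de_log2_effect_range)
            x[n_hub:n_de] += delta[:, None] * gc[None, :]
            effects[n_hub:n_de] = delta
        return ids, x, effects

    mrna_ids, mrna_log2, mrna_eff = expression_layer(
        "NM_", cfg.n_mrna, cfg.n_de_mrna, cfg.n_hub_mrna, cfg.baseline_expr)
    lnc_ids, lnc_log2, lnc_eff = expression_layer(
        "NR_", cfg.n_lncrna, cfg.n_de_lncrna, cfg.n_hub_lncrna,
        cfg.baseline_expr - 1.0)  # lncRNAs sit lower than coding genes

    # batch structure: one factor, levels interleaved within each group so the
    # factor is never confounded with group
    batch = np.empty(n, dtype=object)
    for start, count in ((0, cfg.n_group_a), (cfg.n_group_a, cfg.n_group_b)):
        for j in range(count):
            batch[start + j] = f"B{j % cfg.n_batches + 1}"
    if cfg.batch_shift_sd > 0:
        for lev in sorted(set(batch)):
            mask = batch == lev
            mrna_log2[:, mask] += rng.normal(
                0.0, cfg.batch_shift_sd, size=cfg.n_mrna)[:, None]
            lnc_log2[:, mask] += rng.normal(
                0.0, cfg.batch_shift_sd, size=cfg.n_lncrna)[:, None]

    # OTU layer: coupled OTUs follow the latent factor; raw table = rounded 2^y
    otu_ids = [f"OTU_{i+1:04d}" for i in range(cfg.n_otu)]
    otu_base = rng.normal(cfg.baseline_otu, 1.5, size=cfg.n_otu)
    y = otu_base[:, None] + rng.normal(0.0, cfg.otu_noise_sd,
                                       size=(cfg.n_otu, n))
    otu_eff = np.zeros(cfg.n_otu)
    r_c = cfg.otu_coupling_r
    b_coef = r_c * cfg.otu_noise_sd / np.sqrt(1.0 - r_c ** 2)
    otu_signs = [1 if i % 2 == 0 else -1 for i in range(cfg.n_coupled_otu)]
    for i, sign in enumerate(otu_signs):
        y[i] = otu_base[i] + sign * b_coef * h + rng.normal(
            0.0, cfg.otu_noise_sd, size=n)
        otu_eff[i] = sign * b_coef * hub_effect
    if cfg.n_de_otu > cfg.n_coupled_otu:
        delta = _planted_effects(rng, cfg.n_de_otu - cfg.n_coupled_otu,
                                 *cfg.de_log2_effect_range)
        y[cfg.n_coupled_otu:cfg.n_de_otu] += delta[:, None] * gc[None, :]
        otu_eff[cfg.n_coupled_otu:cfg.n_de_otu] = delta
    otu_counts = np.maximum(0, np.rint(np.exp2(y))).astype(float)

    # --- metadata ---------------------------------------------------------
    groups = [cfg.group_labels[0]] * cfg.n_group_a + \
             [cfg.group_labels[1]] * cfg.n_group_b
    meta = SampleMetadata(
        pd.DataFrame({"group": groups, "labeling": batch},
                     index=pd.Index(sample_ids, name="sample_id")),
        batch_cols=("labeling",))

    # --- gene sets, pooled genes, disease list ---------------------------
    hub_mrna = mrna_ids[:cfg.n_hub_mrna]
    hub_lnc = lnc_ids[:cfg.n_hub_lncrna]
    extra_pool = mrna_ids[cfg.n_hub_mrna:cfg.n_hub_mrna + cfg.n_pooled_extra]
    pooled = list(hub_mrna) + list(extra_pool)

    n_sets = cfg.n_planted_sets
    filler_pool = mrna_ids[cfg.n_de_mrna:]  # background genes, never in query
    # pad planted sets with background genes and build disjoint decoy sets,
    # scaling the padding down when the background pool is small
    fill_each = min(10, (len(filler_pool) // 2) // max(n_sets, 1))
    decoy_size = min(30, (len(filler_pool) - fill_each * n_sets)
                     // max(cfg.n_decoy_sets, 1))
    if cfg.n_decoy_sets and decoy_size < 1:
        raise ValueError("not enough background mRNAs to build decoy gene sets")
    filler_iter = iter(filler_pool)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    planted_names = []
    for s in range(n_sets):
        name = f"GO_RESPONSE_TO_BACTERIUM_{s+1:02d}"
        members = [gid for i, gid in enumerate(pooled) if i % n_sets == s]
        # overlap sets a little, as real GO categories do
        members += [gid for i, gid in enumerate(pooled)
                    if i % n_sets == (s + 1) % n_sets and i % 3 == 0]
        members += [next(filler_iter) for _ in range(fill_each)]
        sets[name] = (f"cellular response to bacterium (planted {s+1})",
                      tuple(dict.fromkeys(members)))
        planted_names.append(name)
    decoy_names = []
    for s in range(cfg.n_decoy_sets):
        name = f"DECOY_PROCESS_{s+1:02d}"
        members = tuple(next(filler_iter) for _ in range(decoy_size))
        sets[name] = (f"unrelated housekeeping process (decoy {s+1})", members)
        decoy_names.append(name)
    gene_sets = GeneSetCollection(sets)

    non_pooled = [gid for gid in mrna_ids if gid not in set(pooled)]
    decoy_disease = list(rng.choice(non_pooled,
                                    size=min(cfg.n_disease_decoys, len(non_pooled)),
                                    replace=False))
    disease_genes = sorted(list(hub_mrna) + decoy_disease)

    # --- manifest ---------------------------------------------------------
    def de_records(ids, effects, n_de):
        return [{"feature_id": ids[i], "log2_effect": float(effects[i]),
                 "direction": int(np.sign(effects[i]) or 1)}
                for i in range(n_de)]

    manifest = GroundTruthManifest(
        de_features={
            "mrna": de_records(mrna_ids, mrna_eff, cfg.n_de_mrna),
            "lncrna": de_records(lnc_ids, lnc_eff, cfg.n_de_lncrna),
            "otu": de_records(otu_ids, otu_eff, cfg.n_de_otu),
        },
        hub_lncrna=list(hub_lnc),
        hub_mrna=list(hub_mrna),
        hub_edges=[(l, m_, cfg.hub_target_r) for l in hub_lnc for m_ in hub_mrna],
        coupled_otus=[(otu_ids[i], otu_signs[i]) for i in range(cfg.n_coupled_otu)],
        otu_couplings=[(l, otu_ids[i], otu_signs[i])
                       for l in hub_lnc for i in range(cfg.n_coupled_otu)],
        pooled_genes=pooled,
        disease_genes=disease_genes,
        planted_set_names=planted_names,
        decoy_set_names=decoy_names,
    )

    def as_matrix(ids, log2_values, layer):
        df = pd.DataFrame(np.exp2(log2_values), index=ids, columns=sample_ids)
        return OmicsMatrix(df, layer, Scale.RAW)

    mrna = as_matrix(mrna_ids, mrna_log2, Layer.MRNA)
    lncrna = as_matrix(lnc_ids, lnc_log2, Layer.LNCRNA)
    otu = OmicsMatrix(pd.DataFrame(otu_counts, index=otu_ids,
                                   columns=sample_ids), Layer.OTU, Scale.RAW)
    return CohortBundle(mrna, lncrna, otu, meta, gene_sets,
                        disease_genes, manifest, cfg)


FIXTURE_FILES = ("mrna.tsv", "lncrna.tsv", "otu.tsv", "metadata.tsv",
                 "gene_sets.gmt", "disease_genes.txt", "manifest.json")


def write_fixture(bundle: CohortBundle, out_dir, force: bool = False) -> list[Path]:
    """Write the bundle as the seven canonical artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    lio.write_matrix(bundle.mrna, out / "mrna.tsv")
    lio.write_matrix(bundle.lncrna, out / "lncrna.tsv")
    lio.write_matrix(bundle.otu, out / "otu.tsv")
    lio.write_metadata(bundle.metadata, out / "metadata.tsv")
    lio.write_gene_sets(bundle.gene_sets, out / "gene_sets.gmt")
    lio.write_gene_list(bundle.disease_genes, out / "disease_genes.txt")
    payload = {"config": asdict(bundle.config),
               "ground_truth": bundle.manifest.to_json()}
    lio.write_json(payload, out / "manifest.json")
    return [out / f for f in FIXTURE_FILES]


def load_fixture(in_dir) -> CohortBundle:
    """Reload a fixture directory written by :func:`write_fixture`."""
    d = Path(in_dir)
    with open(d / "manifest.json") as fh:
        payload = json.load(fh)
    cfg_dict = payload["config"]
    for key in ("de_log2_effect_range", "group_labels"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = SyntheticConfig(**cfg_dict)
    manifest = GroundTruthManifest.from_json(payload["ground_truth"])
    manifest.hub_edges = [tuple(e) for e in manifest.hub_edges]
    manifest.coupled_otus = [tuple(e) for e in manifest.coupled_otus]
    manifest.otu_couplings = [tuple(e) for e in manifest.otu_couplings]
    return CohortBundle(
        mrna=lio.read_expression_matrix(d / "mrna.tsv", Layer.MRNA, Scale.RAW),
        lncrna=lio.read_expression_matrix(d / "lncrna.tsv", Layer.LNCRNA, Scale.RAW),
        otu=lio.read_expression_matrix(d / "otu.tsv", Layer.OTU, Scale.RAW),
        metadata=lio.read_metadata(d / "metadata.tsv", batch_cols=("labeling",)),
        gene_sets=lio.read_gene_sets(d / "gene_sets.gmt"),
        disease_genes=lio.read_gene_list(d / "disease_genes.txt"),
        manifest=manifest,
        config=cfg,
    )


def small_fixture_config(seed: int = 7) -> SyntheticConfig:
    """Desk-scale fixture: same structure, ~5× fewer features and samples."""
    return SyntheticConfig(
        n_group_a=30, n_group_b=28,
        n_mrna=400, n_lncrna=300, n_otu=80,
        n_de_mrna=80, n_de_lncrna=60, n_de_otu=15,
        n_hub_lncrna=12, n_hub_mrna=8,
        n_coupled_otu=3,
        n_pooled_extra=12,
        n_planted_sets=4, n_decoy_sets=4,
        n_disease_decoys=40,
        seed=seed,
    )
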