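"""Seeded generator of EPIC-like whole-blood methylation cohorts with known truth.

The generator emulates the features of a peripheral-blood therapy-response
EWAS that the downstream stages must handle:

* six-leukocyte mixtures (B, CD4T, CD8T, monocytes, neutrophils, NK) with
  Dirichlet-distributed proportions over a set of cell-type discriminating
  reference probes;
* response-associated CpGs planted as a constant shift on the logit
  (M-value) scale so effects never leave [0, 1];
* SNP-affected probes drawn from tri-modal clusters at beta 0.05/0.5/0.95
  with Hardy-Weinberg genotype frequencies;
* covariate-driven methylation shifts (smoking, concomitant methotrexate);
* DAS28 baseline/follow-up trajectories that reproduce the intended
  responder / non-responder label exactly under the clinical decision rule.

Everything is deterministic given the configured seed, and every planted
signal is recorded in a :class:`TruthRecord` so recovery can be scored.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .errors import ValidationError
from .labels import label_response

CELL_TYPES = ("B", "CD4T", "CD8T", "Mono", "Neu", "NK")

#: Mean blood fractions used for the Dirichlet draw: neutrophil-dominant,
#: typical of adult whole blood.
CELL_MEANS = {"B": 0.06, "CD4T": 0.15, "CD8T": 0.08, "Mono": 0.08, "Neu": 0.60, "NK": 0.03}

#: Dirichlet concentration: higher = less between-sample variation.
CELL_CONCENTRATION = 50.0

SNP_CLUSTER_BETAS = (0.05, 0.50, 0.95)

_EPS = 1e-4


def _logit(b: np.ndarray) -> np.ndarray:
    b = np.clip(b, _EPS, 1.0 - _EPS)
    return np.log2(b / (1.0 - b))


def _expit(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + 2.0 ** (-x)), 2.0**x / (2.0**x + 1.0))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror a 92-patient adalimumab-response cohort at desk scale:
    49/92 responders, effect sizes of ~0.8 on the log2-odds scale (beta
    differences of roughly 0.04-0.16 at mid-range methylation), smoking and
    concomitant-methotrexate rates that differ between response groups, and
    measurement plus residual biological noise of SD 0.15 on the logit scale.
    """

    n_samples: int = 92
    n_probes: int = 2000
    n_celltypes: int = 6
    n_informative: int = 20
    delta_logit: float = 0.8
    n_snp_probes: int = 20
    noise_sd: float = 0.15
    #: covariate -> (number of affected probes, logit shift for carriers)
    covariate_effects: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {"smoking": (10, 0.5), "mtx": (10, 0.5)}
    )
    responder_fraction: float = 49.0 / 92.0
    seed: int = 0

    # covariate prevalence per (responder, non-responder) group
    smoking_rates: tuple[float, float] = (0.204, 0.429)
    mtx_rates: tuple[float, float] = (0.857, 0.651)
    female_rates: tuple[float, float] = (0.796, 0.744)
    age_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((52.7, 9.3), (55.4, 12.5))
    das28_baseline_mean_sd: tuple[float, float] = (4.8, 1.2)
    das28_followup_mean_sd: tuple[tuple[float, float], tuple[float, float]] = (
        (2.6, 1.2),
        (5.3, 1.0),
    )

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.n_celltypes != len(CELL_TYPES):
            raise ValidationError(f"n_celltypes must be {len(CELL_TYPES)}")
        if self.n_informative + self.n_snp_probes > self.n_probes:
            raise ValidationError("n_informative + n_snp_probes exceeds n_probes")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValidationError("responder_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for cov, (k, _) in self.covariate_effects.items():
            if cov not in {"smoking", "mtx", "sex", "age"}:
                raise ValidationError(f"unknown covariate in covariate_effects: {cov}")
            if k < 0:
                raise ValidationError("covariate effect probe counts must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort, for scoring recovery downstream."""

    seed: int
    informative_probe_ids: list
    informative_delta: dict  # probe id -> true logit shift in responders
    snp_probe_ids: list
    snp_cluster_means: list
    covariate_probe_ids: dict  # covariate -> probe ids carrying its shift
    cell_proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    labels: pd.Series  # sample id -> 'responder' / 'non_responder'

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": self.seed,
            "informative_probe_ids": list(self.informative_probe_ids),
            "informative_delta": dict(self.informative_delta),
            "snp_probe_ids": list(self.snp_probe_ids),
            "snp_cluster_means": list(self.snp_cluster_means),
            "covariate_probe_ids": {k: list(v) for k, v in self.covariate_probe_ids.items()},
            "cell_proportions": {
                "index": self.cell_proportions.index.tolist(),
                "columns": self.cell_proportions.columns.tolist(),
                "values": self.cell_proportions.to_numpy().tolist(),
            },
            "labels": self.labels.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        props = pd.DataFrame(
            payload["cell_proportions"]["values"],
            index=payload["cell_proportions"]["index"],
            columns=payload["cell_proportions"]["columns"],
        )
        return cls(
            seed=payload["seed"],
            informative_probe_ids=payload["informative_probe_ids"],
            informative_delta=payload["informative_delta"],
            snp_probe_ids=payload["snp_probe_ids"],
            snp_cluster_means=payload["snp_cluster_means"],
            covariate_probe_ids=payload["covariate_probe_ids"],
            cell_proportions=props,
            labels=pd.Series(payload["labels"]),
        )


def generate_reference_profiles(
    n_probes: int, n_discriminating_per_type: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Build a probes x 6 cell-type mean-beta reference matrix.

    For each cell type, ``n_discriminating_per_type`` probes are nearly fully
    methylated (beta 0.9) in that type and nearly unmethylated (0.1) in all
    others; the remaining probes share a per-probe baseline common to every
    type.  Deterministic given ``seed``.
    """
    k = len(CELL_TYPES)
    if n_probes < k * n_discriminating_per_type:
        raise ValidationError(
            f"n_probes={n_probes} too small: need at least "
            f"{k * n_discriminating_per_type} for {n_discriminating_per_type} "
            f"discriminating probes per cell type"
        )
    rng = np.random.default_rng(seed)
    values = np.empty((n_probes, k))
    values[:] = np.nan
    block = k * n_discriminating_per_type
    for t in range(k):
        rows = slice(t * n_discriminating_per_type, (t + 1) * n_discriminating_per_type)
        values[rows, :] = 0.1
        values[rows, t] = 0.9
    baseline = rng.uniform(0.15, 0.85, size=n_probes - block)
    values[block:, :] = baseline[:, None]
    probe_ids = [f"cg9{i:07d}" for i in range(n_probes)]
    return pd.DataFrame(values, index=probe_ids, columns=list(CELL_TYPES))


def _draw_followup(rng, baseline: float, want: str, mean: float, sd: float) -> float:
    """Rejection-sample a follow-up DAS28 whose label equals ``want`` exactly.

    Draws whose decision-rule label is indeterminate or conflicting are
    redrawn, so emitted trajectories are always unambiguous.
    """
    for _ in range(100_000):
        f = float(np.clip(rng.normal(mean, sd), 0.0, 10.0))
        if label_response(baseline, f).label == want:
            return f
    raise RuntimeError("could not draw a follow-up DAS28 matching the intended label")


def generate_cohort(
    config: GeneratorConfig, references: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (beta matrix, sample sheet, probe manifest, truth record).

    The first block of probes is the deconvolution panel: its betas are the
    reference profiles mixed by each sample's true cell proportions.  The
    remaining probes carry a per-probe baseline plus, where planted, the
    response effect, a covariate shift, or a SNP-like tri-modal genotype
    signal.  Logit-normal noise of SD ``config.noise_sd`` is added last
    (skipped entirely at noise_sd=0 so the zero-noise cohort is exact).
    """
    config.validate()
    n_ref = references.shape[0]
    if list(references.columns) != list(CELL_TYPES):
        raise ValidationError(f"references must have columns {CELL_TYPES}")
    n_free = config.n_probes - n_ref - config.n_informative - config.n_snp_probes
    n_cov = sum(k for k, _ in config.covariate_effects.values())
    if n_free < n_cov:
        raise ValidationError(
            "n_probes too small for the requested reference, informative, SNP "
            "and covariate-affected probe blocks"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    # --- response labels -------------------------------------------------
    n_resp = _round_half_up(config.responder_fraction * n)
    if n_resp in (0, n):
        raise ValidationError("responder_fraction leaves one group empty")
    is_resp = np.zeros(n, dtype=bool)
    is_resp[rng.permutation(n)[:n_resp]] = True
    labels = pd.Series(
        np.where(is_resp, "responder", "non_responder"), index=sample_ids, name="response"
    )

    # --- clinical covariates ---------------------------------------------
    def _by_group(rates):
        p = np.where(is_resp, rates[0], rates[1])
        return (rng.random(n) < p).astype(int)

    smoking = _by_group(config.smoking_rates)
    mtx = _by_group(config.mtx_rates)
    sex = _by_group(config.female_rates)  # 1 = female
    (mu_r, sd_r), (mu_n, sd_n) = config.age_mean_sd
    age = np.where(
        is_resp, rng.normal(mu_r, sd_r, size=n), rng.normal(mu_n, sd_n, size=n)
    ).round(1)

    b_mu, b_sd = config.das28_baseline_mean_sd
    das_base = np.clip(rng.normal(b_mu, b_sd, size=n), 1.0, 10.0).round(2)
    (fr_mu, fr_sd), (fn_mu, fn_sd) = config.das28_followup_mean_sd
    das_follow = np.array(
        [
            _draw_followup(
                rng,
                das_base[i],
                "responder" if is_resp[i] else "non_responder",
                fr_mu if is_resp[i] else fn_mu,
                fr_sd if is_resp[i] else fn_sd,
            )
            for i in range(n)
        ]
    ).round(2)

    sheet = pd.DataFrame(
        {
            "das28_baseline": das_base,
            "das28_followup": das_follow,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "mtx": mtx,
            "response": labels.to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- cell proportions and the deconvolution block --------------------
    alpha = np.array([CELL_MEANS[t] for t in CELL_TYPES]) * CELL_CONCENTRATION
    props = rng.dirichlet(alpha, size=n)  # samples x cell types
    beta = np.empty((config.n_probes, n))
    beta[:n_ref, :] = references.to_numpy() @ props.T

    # --- remaining probe blocks ------------------------------------------
    other_ids = [f"cg0{i:07d}" for i in range(config.n_probes - n_ref)]
    probe_ids = list(references.index) + other_ids
    pos = n_ref
    informative_ids = probe_ids[pos : pos + config.n_informative]
    pos += config.n_informative
    snp_ids = probe_ids[pos : pos + config.n_snp_probes]
    pos += config.n_snp_probes
    cov_ids: dict[str, list[str]] = {}
    for cov, (k_cov, _) in config.covariate_effects.items():
        cov_ids[cov] = probe_ids[pos : pos + k_cov]
        pos += k_cov

    baseline = rng.uniform(0.1, 0.9, size=config.n_probes - n_ref)
    beta[n_ref:, :] = baseline[:, None]

    idx = {p: i for i, p in enumerate(probe_ids)}

    # planted response effect: constant shift of logit-beta in responders
    informative_delta = {p: float(config.delta_logit) for p in informative_ids}
    for p in informative_ids:
        row = _logit(beta[idx[p], :])
        row[is_resp] += config.delta_logit
        beta[idx[p], :] = _expit(row)

    # covariate-driven shifts (carriers of the binary covariate; age uses
    # the standardized value)
    cov_values = {"smoking": smoking, "mtx": mtx, "sex": sex}
    if np.std(age) > 0:
        cov_values["age"] = (age - age.mean()) / age.std()
    for cov, (_, shift) in config.covariate_effects.items():
        carrier = cov_values[cov].astype(float)
        for p in cov_ids[cov]:
            beta[idx[p], :] = _expit(_logit(beta[idx[p], :]) + shift * carrier)

    # SNP-like probes: Hardy-Weinberg genotypes at allele frequency 0.5
    geno_p = np.array([0.25, 0.50, 0.25])
    cluster = np.asarray(SNP_CLUSTER_BETAS)
    for p in snp_ids:
        g = rng.choice(3, size=n, p=geno_p)
        beta[idx[p], :] = cluster[g]

    # --- measurement noise on the logit scale -----------------------------
    if config.noise_sd > 0:
        beta = _expit(_logit(beta) + rng.normal(0.0, config.noise_sd, size=beta.shape))
    beta = np.clip(beta, 0.0, 1.0)

    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)

    manifest = _build_manifest(probe_ids)

    truth = TruthRecord(
        seed=config.seed,
        informative_probe_ids=list(informative_ids),
        informative_delta=informative_delta,
        snp_probe_ids=list(snp_ids),
        snp_cluster_means=list(SNP_CLUSTER_BETAS),
        covariate_probe_ids=cov_ids,
        cell_proportions=pd.DataFrame(props, index=sample_ids, columns=list(CELL_TYPES)),
        labels=labels,
    )
    return beta_df, sheet, manifest, truth


_FEATURES = ("TSS", "promoter", "enhancer", "intron", "exon")
_PROBES_PER_GENE = 5
_PROBE_SPACING = 500
_GENE_GAP = 100_000


def _build_manifest(probe_ids: Sequence[str]) -> pd.DataFrame:
    """Lay probes out on autosomes in 5-probe gene blocks with hg19-like positions."""
    n = len(probe_ids)
    chroms, positions, genes, features = [], [], [], []
    chrom_cursor = {}
    for i, pid in enumerate(probe_ids):
        gene_idx = i // _PROBES_PER_GENE
        within = i % _PROBES_PER_GENE
        chrom = f"chr{gene_idx % 22 + 1}"
        if within == 0:
            chrom_cursor[chrom] = chrom_cursor.get(chrom, 10_000) + _GENE_GAP
        base = chrom_cursor[chrom]
        chroms.append(chrom)
        positions.append(base + within * _PROBE_SPACING)
        genes.append(f"GENE{gene_idx:05d}")
        features.append(_FEATURES[within % len(_FEATURES)])
    return pd.DataFrame(
        {"chrom": chroms, "pos": positions, "gene": genes, "feature": features},
        index=pd.Index([str(p) for p in probe_ids], name="probe_id"),
    )


def gene_table_from_manifest(manifest: pd.DataFrame, margin: int = 500) -> pd.DataFrame:
    """Derive gene intervals from a manifest's gene column (block extents +/- margin)."""
    rows = []
    for gene, sub in manifest.dropna(subset=["gene"]).groupby("gene"):
        rows.append(
            {
                "gene": gene,
                "chrom": sub["chrom"].iloc[0],
                "start": max(1, int(sub["pos"].min()) - margin),
                "end": int(sub["pos"].max()) + margin,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(
    outdir: str | os.PathLike,
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    manifest: pd.DataFrame,
    truth: TruthRecord,
) -> dict:
    """Write all four cohort artifacts; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "beta_matrix": os.path.join(outdir, "beta_matrix.tsv"),
        "sample_sheet": os.path.join(outdir, "sample_sheet.csv"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    io.write_beta_matrix(beta, paths["beta_matrix"])
    io.write_sample_sheet(sheet, paths["sample_sheet"])
    io.write_manifest(manifest, paths["manifest"])
    truth.to_json(paths["truth"])
    return paths
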