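"""Synthetic cohort generator for the full analysis chain.

Generates cohorts carrying the statistical structure the pipeline assumes:
depressive symptoms flatten the diurnal cortisol slope, a flattened slope
(and depression) raises the death hazard under a proportional-hazards
model, and depression shifts leukocyte transcript abundance, whose
up-regulated promoters are enriched for an NF-κB-like motif. Every planted
latent quantity is recorded in a truth object so each downstream stage has
a recovery target.

Default calibration (fixed once): 202 patients, 23% above the CES-D
screening cutoff, diurnal log-cortisol slope with marginal mean −0.7 and SD
0.6 (abstract slope units per hour of the sampling schedule), ~64% deaths
under an exponential baseline hazard of 0.35/yr with a 6-year horizon and
90% uniform dropout censoring, 5000 transcripts with 116 planted up- and 57
planted down-regulated at 2-fold (log2 noise SD 0.2, extreme groups of 15
vs 16), and 1200-bp promoters with a background motif density of 2
sites/promoter enriched 1.75-fold in up-regulated genes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import Annotation, write_gmt
from .expression import select_matched_extremes
from .survival import RISK_FACTOR_NAMES, classify_risk
from .tfbs import PWM, PromoterRecord, pwm_from_consensus

__all__ = [
    "CohortConfig",
    "CohortBundle",
    "generate_cohort",
    "generate_cortisol_series",
    "generate_survival_times",
    "generate_expression",
    "generate_promoters",
    "generate_annotations",
    "write_bundle",
    "DEFAULT_SCHEDULE",
]

# five samples per day: waking, +45 min, +8 h, +12 h, bedtime (+16 h)
DEFAULT_SCHEDULE = (0.0, 0.75, 8.0, 12.0, 16.0)


@dataclass(frozen=True)
class CohortConfig:
    """All calibration constants for one synthetic cohort."""

    n_patients: int = 202
    p_depressed: float = 0.23
    # (mean, sd) of CES-D within the non-depressed and depressed groups;
    # scores truncated to [0, cutoff) and [cutoff, 60]
    cesd_means_sds: tuple[tuple[float, float], tuple[float, float]] = (
        (7.5, 4.5),
        (21.0, 4.5),
    )
    cesd_cutoff: float = 16.0
    slope_mean: float = -0.7  # marginal mean, log-cortisol per hour
    slope_sd: float = 0.6  # marginal SD
    slope_noise_sd: float = 0.25  # residual SD of log-cortisol around the line
    cesd_slope_effect: float = 0.3  # slope shift (flattening) per depressed indicator
    intercept_mean: float = 2.5  # log-cortisol at waking
    intercept_sd: float = 0.4
    baseline_hazard: float = 0.35  # events/year at the mean linear predictor
    weibull_shape: float = 1.0  # 1 = exponential baseline
    log_hr_slope: float = math.log(1.88)  # per slope unit
    log_hr_cesd: float = math.log(1.4)  # direct effect of the depressed indicator
    censor_horizon: float = 6.0  # years
    dropout_prob: float = 0.9
    n_genes: int = 5000
    n_up: int = 116
    n_down: int = 57
    planted_fc: float = 2.0
    expr_noise_sd: float = 0.2  # log2 units
    n_expr_high: int = 15
    n_expr_low: int = 16
    promoter_len: int = 1200
    motif_consensus: str = "GGGACTTTCC"  # NF-κB-like planted consensus
    motif_density_bg: float = 2.0  # planted sites per background promoter
    motif_enrichment: float = 1.75  # density fold in up-regulated promoters
    car_bump: float = 0.0  # cortisol awakening response on the +45-min sample
    bedtime_hours: float = 16.0
    seed: int = 0

    def validate(self) -> None:
        def check(cond, name, msg):
            if not cond:
                raise ValueError(f"invalid CohortConfig.{name}: {msg}")

        check(self.n_patients >= 0, "n_patients", "must be >= 0")
        check(0 <= self.p_depressed <= 1, "p_depressed", "must be in [0, 1]")
        check(0 <= self.dropout_prob <= 1, "dropout_prob", "must be in [0, 1]")
        check(self.slope_sd >= 0, "slope_sd", "must be >= 0")
        check(self.slope_noise_sd >= 0, "slope_noise_sd", "must be >= 0")
        check(self.baseline_hazard > 0, "baseline_hazard", "must be > 0")
        check(self.censor_horizon >= 0, "censor_horizon", "must be >= 0")
        check(self.n_genes >= 0, "n_genes", "must be >= 0")
        check(
            self.n_up + self.n_down <= self.n_genes,
            "n_up",
            "n_up + n_down must not exceed n_genes",
        )
        check(self.planted_fc > 1, "planted_fc", "must be > 1")
        check(self.expr_noise_sd >= 0, "expr_noise_sd", "must be >= 0")
        check(
            self.promoter_len >= len(self.motif_consensus),
            "promoter_len",
            "must fit the motif",
        )
        check(self.motif_density_bg >= 0, "motif_density_bg", "must be >= 0")
        check(self.motif_enrichment > 0, "motif_enrichment", "must be > 0")


@dataclass
class CohortBundle:
    """Everything one simulated study produces, plus the latent truth."""

    config: CohortConfig
    patients: pd.DataFrame
    saliva: pd.DataFrame
    survival: pd.DataFrame
    expression: pd.DataFrame  # genes × expression-subgroup samples, array scale
    promoters: list[PromoterRecord]
    annotations: list[Annotation]
    truth: dict


def generate_cortisol_series(
    true_slope: float,
    true_intercept: float,
    noise_sd: float,
    rng: np.random.Generator,
    schedule=DEFAULT_SCHEDULE,
    n_days: int = 3,
    car_bump: float = 0.0,
) -> pd.DataFrame:
    """Simulate timed saliva samples on a log-linear diurnal decline.

    log-concentration = intercept + slope·t + Normal(0, noise_sd), with an
    optional awakening-response bump added to the +45-minute sample.
    Concentrations are strictly positive by construction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    sched = np.asarray(schedule, dtype=float)
    if np.any(np.diff(sched) <= 0):
        raise ValueError("schedule must be strictly increasing within a day")
    rows = []
    for day in range(1, n_days + 1):
        logc = true_intercept + true_slope * sched
        if car_bump:
            bump = np.zeros_like(sched)
            if sched.size > 1:
                bump[1] = car_bump
            logc = logc + bump
        logc = logc + rng.normal(0.0, noise_sd, size=sched.size)
        for idx, (t, lc) in enumerate(zip(sched, logc), start=1):
            rows.append((day, idx, t, math.exp(lc)))
    return pd.DataFrame(rows, columns=["day", "sample_index", "t", "cortisol"])


def generate_survival_times(
    linear_predictor,
    baseline_hazard: float,
    censor_horizon: float,
    rng: np.random.Generator,
    dropout_prob: float = 0.9,
    weibull_shape: float = 1.0,
) -> pd.DataFrame:
    """Event/censoring times under a proportional-hazards model.

    Event times follow a Weibull with cumulative hazard
    ``baseline_hazard · t^shape · exp(lp)`` (shape 1 = exponential).
    Censoring is uniform dropout on (0, horizon) with probability
    `dropout_prob`, administrative at the horizon otherwise. A zero horizon
    censors everyone at 0; a negative horizon is an error.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    if censor_horizon < 0:
        raise ValueError("censor_horizon must be >= 0")
    lp = np.asarray(linear_predictor, dtype=float)
    n = lp.size
    e = rng.exponential(1.0, size=n)
    t_event = (e / (baseline_hazard * np.exp(lp))) ** (1.0 / weibull_shape)
    drop = rng.random(n) < dropout_prob
    c = np.where(drop, rng.uniform(0.0, censor_horizon or 1.0, n), censor_horizon)
    if censor_horizon == 0:
        c = np.zeros(n)
    time = np.minimum(t_event, c)
    event = t_event <= c
    if censor_horizon == 0:
        event[:] = False
    return pd.DataFrame({"time": time, "event": event, "true_event_time": t_event})


def generate_expression(
    group,
    n_genes: int,
    n_up: int,
    n_down: int,
    planted_fc: float,
    noise_sd: float,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
    covariate_effect_sd: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Array-scale expression matrix with planted group differences.

    Planted genes differ by ±log2(`planted_fc`) in group means on the log2
    scale (after any covariate effects); all other genes differ by 0.
    Returns (matrix on the positive array-intensity scale, truth dict with
    the planted up/down gene sets).
    """
    g = np.asarray(group, dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("group must contain both levels")
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down must not exceed n_genes")
    n_samples = g.size
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    base = rng.normal(7.0, 1.0, size=n_genes)
    effect = np.zeros(n_genes)
    up_set, down_set = [], []
    if planted_fc != 1.0:
        delta = math.log2(planted_fc)
        idx = rng.permutation(n_genes)[: n_up + n_down]
        effect[idx[:n_up]] = delta
        effect[idx[n_up:]] = -delta
        up_set = [genes[i] for i in sorted(idx[:n_up])]
        down_set = [genes[i] for i in sorted(idx[n_up:])]
    log2x = base[:, None] + effect[:, None] * g[None, :]
    if covariates is not None and covariates.shape[1] > 0:
        Z = covariates.to_numpy(dtype=float)
        Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
        coefs = rng.normal(0.0, covariate_effect_sd, size=(n_genes, Z.shape[1]))
        log2x = log2x + coefs @ Z.T
    if noise_sd > 0:
        log2x = log2x + rng.normal(0.0, noise_sd, size=log2x.shape)
    matrix = pd.DataFrame(
        2.0**log2x, index=genes, columns=[f"S{j + 1:02d}" for j in range(n_samples)]
    )
    truth = {"up": up_set, "down": down_set, "group": list(map(int, g))}
    return matrix, truth


def generate_promoters(
    genes,
    promoter_len: int,
    motif: PWM | str,
    density_bg: float,
    enriched_set,
    enrichment: float,
    rng: np.random.Generator,
    downstream: int = 200,
) -> tuple[list[PromoterRecord], dict]:
    """Uniform-background promoters with Poisson-planted consensus sites.

    Background genes carry Poisson(`density_bg`) exact-consensus occurrences
    at uniform non-overlapping positions; genes in `enriched_set` carry
    Poisson(`density_bg` · `enrichment`). The TSS sits `downstream` bp from
    the 3' end, so a promoter of 1200 bp spans −1000…+200.
    """
    consensus = motif.consensus if isinstance(motif, PWM) else str(motif).upper()
    L = len(consensus)
    if L > promoter_len:
        raise ValueError(f"motif ({L} bp) longer than promoter ({promoter_len} bp)")
    enriched = set(enriched_set)
    tss = promoter_len - downstream
    records = []
    planted_counts = {}
    cons_codes = np.frombuffer(consensus.encode(), dtype=np.uint8)
    for gene in genes:
        seq = rng.integers(0, 4, size=promoter_len)
        dens = density_bg * (enrichment if gene in enriched else 1.0)
        k = rng.poisson(dens)
        placed = []
        attempts = 0
        while len(placed) < k and attempts < 200 * (k + 1):
            pos = int(rng.integers(0, promoter_len - L + 1))
            if all(abs(pos - q) >= L for q in placed):
                placed.append(pos)
            attempts += 1
        base_map = np.frombuffer(b"ACGT", dtype=np.uint8)
        arr = base_map[seq]
        for pos in placed:
            arr[pos : pos + L] = cons_codes
        records.append(PromoterRecord(gene, arr.tobytes().decode(), tss))
        planted_counts[gene] = len(placed)
    return records, {"planted_sites": planted_counts, "consensus": consensus}


def generate_annotations(
    genes, up_set, down_set, rng: np.random.Generator, n_random_terms: int = 5
) -> list[Annotation]:
    """Small synthetic term annotation: inflammation/immune terms seeded with
    up-regulated genes, an adhesion term seeded with down-regulated genes,
    plus random null terms."""
    genes = list(genes)
    terms = []

    def seeded(term, label, seed_genes, frac, n_extra):
        k = max(1, int(len(seed_genes) * frac)) if seed_genes else 0
        core = list(rng.choice(seed_genes, size=k, replace=False)) if k else []
        n_extra = min(n_extra, len(genes))
        extra = list(rng.choice(genes, size=n_extra, replace=False))
        return Annotation(term, label, frozenset(core + extra))

    if up_set:
        terms.append(seeded("SYN:0001", "inflammatory response", list(up_set), 0.5, 40))
        terms.append(seeded("SYN:0002", "immune response", list(up_set), 0.35, 60))
    if down_set:
        terms.append(seeded("SYN:0003", "cell adhesion", list(down_set), 0.5, 40))
    for i in range(n_random_terms):
        size = min(int(rng.integers(30, 120)), len(genes))
        terms.append(
            Annotation(
                f"SYN:1{i:03d}",
                f"null term {i + 1}",
                frozenset(rng.choice(genes, size=size, replace=False)),
            )
        )
    return terms


def _generate_patients(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    (m0, s0), (m1, s1) = cfg.cesd_means_sds
    depressed = rng.random(n) < cfg.p_depressed
    cesd = np.where(
        depressed,
        np.clip(rng.normal(m1, s1, n), cfg.cesd_cutoff, 60.0),
        np.clip(rng.normal(m0, s0, n), 0.0, cfg.cesd_cutoff - 0.1),
    )
    risk_probs = {
        "karnofsky_lt80": 0.09,
        "calcium_ge10": 0.05,
        "low_hemoglobin": 0.40,
        "high_ldh": 0.05,
        "prior_radiation": 0.10,
        "mets_ge2": 0.64,
        "interval_le1yr": 0.60,
    }
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "age": np.round(rng.normal(59, 10, n), 1),
            "sex": np.where(rng.random(n) < 0.77, "M", "F"),
            "ethnicity": rng.choice(
                ["white", "black", "hispanic", "other"], size=n, p=[0.8, 0.1, 0.07, 0.03]
            ),
            "education_years": np.round(np.clip(rng.normal(14, 2.5, n), 6, 22), 0),
            "married": (rng.random(n) < 0.7).astype(int),
            "bmi": np.round(np.clip(rng.normal(28, 5, n), 16, 55), 1),
            "smoking": (rng.random(n) < 0.45).astype(int),
            "cesd": np.round(cesd, 1),
            "depressed": depressed.astype(int),
        }
    )
    counts = np.zeros(n, dtype=int)
    for name in RISK_FACTOR_NAMES:
        v = (rng.random(n) < risk_probs[name]).astype(int)
        df[name] = v
        counts += v
    df["risk_count"] = counts
    df["risk_group"] = [classify_risk(int(c)) for c in counts]
    return df


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Simulate one full cohort; deterministic for a fixed config seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    keys = ["patients", "slopes", "saliva", "survival", "expression", "promoters", "gmt"]
    rngs = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))

    patients = _generate_patients(config, rngs["patients"])
    n = len(patients)

    # latent diurnal slopes: marginal mean/SD kept at config values while the
    # depressed group is flattened by cesd_slope_effect
    dep = patients["depressed"].to_numpy() if n else np.empty(0)
    eff = config.cesd_slope_effect
    p = config.p_depressed
    mu_base = config.slope_mean - p * eff
    var_base = max(config.slope_sd**2 - eff**2 * p * (1 - p), 1e-12)
    true_slope = (
        rngs["slopes"].normal(mu_base, math.sqrt(var_base), n) + eff * dep
        if n
        else np.empty(0)
    )
    true_intercept = rngs["slopes"].normal(
        config.intercept_mean, config.intercept_sd, n
    )

    saliva_frames = []
    for pid, sl, ic in zip(patients["patient_id"], true_slope, true_intercept):
        ser = generate_cortisol_series(
            sl,
            ic,
            config.slope_noise_sd,
            rngs["saliva"],
            schedule=(0.0, 0.75, 8.0, 12.0, config.bedtime_hours),
            car_bump=config.car_bump,
        )
        ser.insert(0, "patient_id", pid)
        saliva_frames.append(ser)
    saliva = (
        pd.concat(saliva_frames, ignore_index=True)
        if saliva_frames
        else pd.DataFrame(columns=["patient_id", "day", "sample_index", "t", "cortisol"])
    )

    lp = config.log_hr_slope * (true_slope - config.slope_mean) + config.log_hr_cesd * dep
    surv = generate_survival_times(
        lp,
        config.baseline_hazard,
        config.censor_horizon,
        rngs["survival"],
        dropout_prob=config.dropout_prob,
        weibull_shape=config.weibull_shape,
    )
    surv.insert(0, "patient_id", patients["patient_id"].to_numpy())
    survival = surv[["patient_id", "time", "event"]].copy()
    survival["event"] = survival["event"].astype(int)
    # guard the time > 0 invariant (uniform dropout can draw arbitrarily small)
    survival["time"] = np.maximum(survival["time"], 1e-6)

    # expression subgroup: extreme CES-D groups, matched where feasible
    truth_expr: dict = {"up": [], "down": []}
    expression = pd.DataFrame()
    expr_samples: list[str] = []
    if config.n_genes and n:
        try:
            high, low = select_matched_extremes(
                patients, k_high=config.n_expr_high, k_low=config.n_expr_low
            )
        except ValueError:
            ordered = patients.sort_values("cesd", kind="stable")
            low = list(ordered["patient_id"].head(config.n_expr_low))
            high = list(ordered["patient_id"].tail(config.n_expr_high))
        expr_samples = list(high) + list(low)
        group = np.array([1] * len(high) + [0] * len(low))
        pat_idx = patients.set_index("patient_id")
        covs = pat_idx.loc[expr_samples, ["age", "bmi"]].reset_index(drop=True)
        expression, truth_expr = generate_expression(
            group,
            config.n_genes,
            config.n_up,
            config.n_down,
            config.planted_fc,
            config.expr_noise_sd,
            rngs["expression"],
            covariates=covs,
        )
        expression.columns = expr_samples

    promoters: list[PromoterRecord] = []
    truth_prom: dict = {}
    if config.n_genes:
        genes = list(expression.index) if len(expression) else [
            f"G{i:05d}" for i in range(1, config.n_genes + 1)
        ]
        promoters, truth_prom = generate_promoters(
            genes,
            config.promoter_len,
            config.motif_consensus,
            config.motif_density_bg,
            set(truth_expr["up"]),
            config.motif_enrichment,
            rngs["promoters"],
        )

    annotations = (
        generate_annotations(
            list(expression.index), truth_expr["up"], truth_expr["down"], rngs["gmt"]
        )
        if len(expression)
        else []
    )

    truth = {
        "true_slope": dict(zip(patients["patient_id"], map(float, true_slope))),
        "true_intercept": dict(zip(patients["patient_id"], map(float, true_intercept))),
        "linear_predictor": dict(zip(patients["patient_id"], map(float, lp))),
        "true_event_time": dict(
            zip(patients["patient_id"], map(float, surv["true_event_time"]))
        ),
        "de_up": truth_expr["up"],
        "de_down": truth_expr["down"],
        "expression_samples": expr_samples,
        "promoters": truth_prom,
    }
    return CohortBundle(
        config=config,
        patients=patients,
        saliva=saliva,
        survival=survival,
        expression=expression,
        promoters=promoters,
        annotations=annotations,
        truth=truth,
    )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle to TSV/FASTA/GMT/JSON files; byte-identical per seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def tsv(name, df, index=False):
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p

    tsv("patients.tsv", bundle.patients)
    tsv("saliva.tsv", bundle.saliva)
    tsv("survival.tsv", bundle.survival)
    if len(bundle.expression):
        expr = bundle.expression.copy()
        expr.index.name = "gene"
        tsv("expression.tsv", expr, index=True)
    if bundle.promoters:
        recs = [
            SeqRecord(
                Seq(r.sequence),
                id=r.gene_id,
                description=f"tss_offset={r.tss_offset}",
            )
            for r in bundle.promoters
        ]
        p = out / "promoters.fasta"
        SeqIO.write(recs, str(p), "fasta")
        paths["promoters.fasta"] = p
    if bundle.annotations:
        p = out / "annotations.gmt"
        p.write_text(write_gmt(bundle.annotations))
        paths["annotations.gmt"] = p
    p = out / "truth.json"
    p.write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    paths["truth.json"] = p
    p = out / "config.json"
    p.write_text(json.dumps(dataclasses.asdict(bundle.config), indent=1, sort_keys=True))
    paths["config.json"] = p
    return paths


def read_promoters_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read promoters written by `write_bundle` (header carries tss_offset)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tss = None
        for tok in rec.description.split():
            if tok.startswith("tss_offset="):
                tss = int(tok.split("=", 1)[1])
        if tss is None:
            raise ValueError(f"{rec.id}: FASTA header lacks tss_offset=<int>")
        records.append(PromoterRecord(rec.id, str(rec.seq), tss))
    return records
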