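"""Synthetic two-environment FPKM matrices, transcript sequences and traits.

The generator emulates the statistical structure of a two-site population
transcriptome: lognormal FPKM baselines, class-dependent dispersion
(lncRNAs noisier than mRNAs, driving higher expression diversity E_d),
class-dependent detection-limit dropout (lncRNAs detected in fewer
individuals, driving lower expression frequency), planted between-environment fold
changes, planted correlated lncRNA-mRNA modules with shared or
environment-specific scope, and a quantitative trait driven by a known
mRNA subset.  Every planted signal is recorded in a
:class:`SimulationTruth` so downstream stages can be scored against
ground truth.

One global seed drives everything; per-stage sub-streams are derived with
``numpy.random.SeedSequence(seed).spawn`` so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import ExpressionMatrix, LNCRNA, MRNA
from .sequence_qc import longest_orf

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_expression",
    "simulate_sequences",
    "simulate_trait",
]

_LN2 = float(np.log(2.0))
# stage order fixes each spawned sub-stream's identity
_STAGES = ("expression", "sequences", "trait")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed."""
    if stage not in _STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; have {_STAGES}")
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES.index(stage)])


@dataclass
class SimulationConfig:
    """Conditions of the simulated two-environment field experiment.

    Defaults mirror the motivating study design: 40 individuals per site,
    a lncRNA:mRNA mix, lncRNAs with larger within-environment log-scale
    spread (higher E_d) and higher dropout (lower expression frequency),
    10% of features with a planted 2x environment effect, diversity
    inflation in the stress environment, and both shared and
    environment-specific co-expression modules.
    """

    n_individuals_per_env: int = 40
    n_lncRNA: int = 600
    n_mRNA: int = 900
    baseline_log_mean: float = 1.0   # natural-log FPKM units
    feature_log_mean_sd: float = 1.0  # between-feature spread of baselines
    baseline_log_sd_mRNA: float = 0.6
    baseline_log_sd_lncRNA: float = 0.9
    dropout_prob_mRNA: float = 0.05
    dropout_prob_lncRNA: float = 0.25
    frac_DE: float = 0.10
    de_log2fc: float = 2.0
    frac_diversity_inflated: float = 0.25
    diversity_inflation_env2: float = 1.8
    n_modules_shared: int = 2
    n_modules_env_specific: int = 2
    module_size_lncRNA: int = 5
    module_size_mRNA: int = 8
    module_latent_sd: float = 5.0
    n_trait_genes: int = 5
    trait_noise_sd: float = 0.5
    seed: int = 0
    env_names: tuple[str, str] = ("env1", "env2")

    def validate(self) -> None:
        for name in ("dropout_prob_mRNA", "dropout_prob_lncRNA", "frac_DE",
                     "frac_diversity_inflated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        for name in ("n_individuals_per_env", "n_lncRNA", "n_mRNA",
                     "n_modules_shared", "n_modules_env_specific",
                     "module_size_lncRNA", "module_size_mRNA", "n_trait_genes"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ConfigurationError(f"{name} must be a count >= 0, got {v}")
        for name in ("feature_log_mean_sd", "baseline_log_sd_mRNA",
                     "baseline_log_sd_lncRNA", "module_latent_sd",
                     "trait_noise_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.diversity_inflation_env2 <= 0:
            raise ConfigurationError(
                f"diversity_inflation_env2 must be > 0, got "
                f"{self.diversity_inflation_env2}")
        if self.n_trait_genes > self.n_mRNA:
            raise ConfigurationError(
                f"n_trait_genes ({self.n_trait_genes}) exceeds n_mRNA "
                f"({self.n_mRNA})")
        n_mod = self.n_modules_shared + self.n_modules_env_specific
        if n_mod * self.module_size_lncRNA > self.n_lncRNA:
            raise ConfigurationError(
                "module memberships exceed n_lncRNA: "
                f"{n_mod} x {self.module_size_lncRNA} > {self.n_lncRNA}")
        if n_mod * self.module_size_mRNA > self.n_mRNA:
            raise ConfigurationError(
                "module memberships exceed n_mRNA: "
                f"{n_mod} x {self.module_size_mRNA} > {self.n_mRNA}")
        if len(self.env_names) != 2 or self.env_names[0] == self.env_names[1]:
            raise ConfigurationError(
                f"env_names must be 2 distinct labels, got {self.env_names}")


@dataclass
class SimulationTruth:
    """Ground truth of every planted signal, keyed by feature id."""

    de_features: dict[str, int] = field(default_factory=dict)  # id -> sign
    diversity_inflated_features: set[str] = field(default_factory=set)
    # id -> (module index, scope in {"shared", "env1", "env2"})
    module_assignments: dict[str, tuple[int, str]] = field(default_factory=dict)
    module_scopes: dict[int, str] = field(default_factory=dict)
    trait_genes: dict[str, float] = field(default_factory=dict)  # id -> loading

    def module_pairs(self, scope: str | None = None) -> set[tuple[str, str]]:
        """All planted within-module (lncRNA, mRNA) pairs, optionally by scope."""
        by_module: dict[int, list[str]] = {}
        for fid, (mod, sc) in self.module_assignments.items():
            if scope is None or sc == scope:
                by_module.setdefault(mod, []).append(fid)
        pairs = set()
        for members in by_module.values():
            lncs = [f for f in members if f.startswith("lnc")]
            mrnas = [f for f in members if f.startswith("mrna")]
            pairs.update((l, m) for l in lncs for m in mrnas)
        return pairs

    def to_json_dict(self) -> dict:
        return {
            "de_features": self.de_features,
            "diversity_inflated_features": sorted(self.diversity_inflated_features),
            "module_assignments": {k: list(v) for k, v in self.module_assignments.items()},
            "module_scopes": {str(k): v for k, v in self.module_scopes.items()},
            "trait_genes": self.trait_genes,
        }


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Generate one two-environment FPKM matrix plus its ground truth.

    Model, per feature f and individual i in environment e:

    ``log FPKM = mu_f + s_f * de * [e == env2] + z_{m(f),e,i} + eps``

    with ``eps ~ N(0, sd_class)`` (sd multiplied by the diversity
    inflation factor for inflated features in env2), module latent
    ``z ~ N(0, module_latent_sd)`` shared by members in the module's
    scoped environment(s), followed by detection-limit censoring: the
    FPKM is recorded as 0 when log FPKM falls below the class detection
    threshold (the ``dropout_prob`` quantile of the class's reference
    marginal).  DE and diversity-inflated sets are drawn disjoint so
    the planted mean log2 E_p ratio of an uncensored DE feature stays
    exactly the signed ``de_log2fc``.
    """
    config.validate()
    rng = stage_rng(config.seed, "expression")
    n_env = config.n_individuals_per_env
    if n_env < 2:
        raise ConfigurationError(
            f"n_individuals_per_env must be >= 2, got {n_env}")
    n_lnc, n_mrna = config.n_lncRNA, config.n_mRNA
    n_feat = n_lnc + n_mrna
    if n_feat == 0:
        raise ConfigurationError("no features: n_lncRNA + n_mRNA == 0")

    lnc_ids = [f"lnc_{i:05d}" for i in range(n_lnc)]
    mrna_ids = [f"mrna_{i:05d}" for i in range(n_mrna)]
    feature_ids = np.array(lnc_ids + mrna_ids)
    is_lnc = np.arange(n_feat) < n_lnc
    env1, env2 = config.env_names
    individuals = [f"{env1}_{i:03d}" for i in range(n_env)] + \
                  [f"{env2}_{i:03d}" for i in range(n_env)]
    env_of = np.array([env1] * n_env + [env2] * n_env)

    truth = SimulationTruth()

    # per-feature baselines (natural log scale)
    mu = config.baseline_log_mean + \
        config.feature_log_mean_sd * rng.standard_normal(n_feat)

    # planted environment effect: disjoint from diversity inflation
    n_de = int(round(config.frac_DE * n_feat))
    n_div = int(round(config.frac_diversity_inflated * n_feat))
    special = rng.choice(n_feat, size=min(n_de + n_div, n_feat), replace=False)
    de_idx = special[:n_de]
    div_idx = special[n_de:n_de + n_div]
    de_sign = rng.choice([-1, 1], size=n_de)
    for j, s in zip(de_idx, de_sign):
        truth.de_features[feature_ids[j]] = int(s)
    truth.diversity_inflated_features = set(feature_ids[div_idx])

    delta = np.zeros(n_feat)
    delta[de_idx] = de_sign * config.de_log2fc * _LN2

    # class-dependent within-environment noise sd, inflated in env2
    sd = np.where(is_lnc, config.baseline_log_sd_lncRNA,
                  config.baseline_log_sd_mRNA)
    sd_env2 = sd.copy()
    sd_env2[div_idx] *= config.diversity_inflation_env2

    n_cols = 2 * n_env
    log_x = mu[:, None] + np.where(env_of == env2, delta[:, None], 0.0)
    eps_sd = np.where(env_of == env2, sd_env2[:, None], sd[:, None])
    log_x = log_x + eps_sd * rng.standard_normal((n_feat, n_cols))

    # planted co-expression modules (disjoint memberships, drawn from
    # features outside the DE/diversity special sets where possible)
    n_modules = config.n_modules_shared + config.n_modules_env_specific
    scopes = ["shared"] * config.n_modules_shared + \
             [env1 if k % 2 == 0 else env2
              for k in range(config.n_modules_env_specific)]
    avoid = set(special.tolist())
    free_lnc = [j for j in range(n_lnc) if j not in avoid]
    free_mrna = [j for j in range(n_lnc, n_feat) if j not in avoid]
    need_l = n_modules * config.module_size_lncRNA
    need_m = n_modules * config.module_size_mRNA
    if len(free_lnc) < need_l or len(free_mrna) < need_m:
        # fall back to drawing from the full class pools
        free_lnc = list(range(n_lnc))
        free_mrna = list(range(n_lnc, n_feat))
    pick_l = rng.choice(free_lnc, size=need_l, replace=False)
    pick_m = rng.choice(free_mrna, size=need_m, replace=False)
    for mod in range(n_modules):
        scope = scopes[mod]
        truth.module_scopes[mod] = scope
        members = np.concatenate([
            pick_l[mod * config.module_size_lncRNA:(mod + 1) * config.module_size_lncRNA],
            pick_m[mod * config.module_size_mRNA:(mod + 1) * config.module_size_mRNA],
        ]).astype(int)
        for j in members:
            truth.module_assignments[feature_ids[j]] = (mod, scope)
        latent = rng.standard_normal(n_cols) * config.module_latent_sd
        if scope == "shared":
            mask = np.ones(n_cols, dtype=bool)
        else:
            mask = env_of == scope
        log_x[members[:, None], np.flatnonzero(mask)[None, :]] += \
            latent[mask][None, :]

    fpkm = np.exp(log_x)

    # class-dependent dropout as detection-limit censoring: a value is
    # unobserved (0) when its log-FPKM falls below the class detection
    # threshold, set at the dropout-probability quantile of the class's
    # reference (env1, no plants) marginal log-FPKM distribution.  This
    # links detection to expression the way FPKM zeros arise in real
    # data, gives features a realistic spread of expression frequencies,
    # and keeps the class marginal dropout rate at the configured value.
    from scipy.stats import norm as _norm

    def _tau(p_drop: float, class_sd: float) -> float:
        if p_drop <= 0:
            return -np.inf
        if p_drop >= 1:
            return np.inf
        total_sd = float(np.hypot(config.feature_log_mean_sd, class_sd))
        return config.baseline_log_mean + total_sd * _norm.ppf(p_drop)

    tau = np.where(is_lnc,
                   _tau(config.dropout_prob_lncRNA,
                        config.baseline_log_sd_lncRNA),
                   _tau(config.dropout_prob_mRNA,
                        config.baseline_log_sd_mRNA))
    fpkm[log_x < tau[:, None]] = 0.0

    # trait genes: unit loadings, drawn from consistently detected mRNAs
    # (a measurable physiological trait is driven by genes that are
    # actually expressed across the population, mirroring the
    # median-FPKM>0 eligibility the trait screen itself applies)
    if config.n_trait_genes > 0:
        mrna_fpkm = fpkm[n_lnc:]
        detected = (mrna_fpkm > 0).sum(axis=1)
        # keep plants disjoint: a trait gene carries no other planted
        # signal, so each planted effect can be scored in isolation
        planted = set(truth.de_features) | truth.diversity_inflated_features \
            | set(truth.module_assignments)
        full = [i for i in range(n_mrna)
                if detected[i] == n_cols and mrna_ids[i] not in planted]
        if len(full) < config.n_trait_genes:
            order = np.argsort(-detected, kind="stable")
            full = [int(i) for i in order[:config.n_trait_genes]]
        tg_idx = rng.choice(full, size=config.n_trait_genes, replace=False)
        truth.trait_genes = {mrna_ids[i]: 1.0 for i in tg_idx}

    values = pd.DataFrame(fpkm, index=pd.Index(feature_ids, name="feature_id"),
                          columns=individuals)
    feature_class = pd.Series(
        np.where(is_lnc, LNCRNA, MRNA), index=values.index, name="class")
    environment = pd.Series(env_of, index=pd.Index(individuals,
                            name="individual_id"), name="environment")
    matrix = ExpressionMatrix(values=values, feature_class=feature_class,
                              environment=environment)
    return matrix, truth


# ---------------------------------------------------------------------------
# transcript sequences

_BASES_AT = np.array(list("AT"))
_BASES_GC = np.array(list("GC"))
_STOP_CODONS = ("TAA", "TAG", "TGA")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    pick_gc = rng.random(length) < gc
    halves = rng.integers(0, 2, size=length)
    chars = np.where(pick_gc, _BASES_GC[halves], _BASES_AT[halves])
    return "".join(chars)


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        c = _random_sequence(rng, 3, gc)
        if c not in _STOP_CODONS and c != "ATG":
            return c


def _long_orf_spans(seq: str, min_len: int) -> list[tuple[int, int, bool]]:
    """Forward-coordinate (start, end, on_forward_strand) spans of every
    complete ORF of at least ``min_len`` nt on either strand."""
    from .sequence_qc import reverse_complement

    spans = []
    n = len(seq)
    for forward, s in ((True, seq), (False, reverse_complement(seq))):
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in _STOP_CODONS:
                    if i + 3 - start >= min_len:
                        if forward:
                            spans.append((start, i + 3, True))
                        else:
                            spans.append((n - (i + 3), n - start, False))
                    start = None
    return spans


def _disrupt_orfs(seq: str, min_len: int, rng: np.random.Generator,
                  max_rounds: int = 200) -> str:
    """Mutate a mid-ORF codon into a stop until no six-frame ORF reaches
    ``min_len``; each split roughly halves the offending ORF, so the
    loop converges in O(log length) rounds."""
    from .sequence_qc import reverse_complement

    chars = list(seq)
    for _ in range(max_rounds):
        spans = _long_orf_spans("".join(chars), min_len)
        if not spans:
            return "".join(chars)
        # one span per round, random codon position: overlapping ORFs on
        # opposite strands can undo each other's fix at a fixed position
        start, end, forward = spans[0]
        n_codons = (end - start) // 3
        k = int(rng.integers(0, n_codons - 1))  # any codon but the stop
        pos = start + 3 * k
        stop = _STOP_CODONS[int(rng.integers(0, 3))]
        if not forward:
            stop = reverse_complement(stop)
        chars[pos : pos + 3] = list(stop)
    raise ConfigurationError(
        f"could not suppress all ORFs >= {min_len} nt after {max_rounds} rounds")


def simulate_sequences(
    n_noncoding: int,
    n_coding: int,
    length_range: tuple[int, int] = (200, 600),
    gc_noncoding: float = 0.46,
    gc_coding: float = 0.51,
    seed: int = 0,
    min_orf_bp: int = 150,
) -> list[tuple[str, str]]:
    """Generate (id, sequence) pairs with controlled ORF content and GC.

    Coding sequences carry an embedded forward-strand ORF of at least
    ``min_orf_bp`` nt (start codon, in-frame stop, no internal in-frame
    stop) at a random offset; noncoding sequences are screened by the
    generator — any chance six-frame ORF reaching ``min_orf_bp`` is
    disrupted by mutating a mid-ORF codon into a stop — so their longest
    ORF is guaranteed below ``min_orf_bp`` at any sequence length.  Base
    composition is uniform over A/C/G/T conditioned on the target GC
    fraction; lengths are uniform over ``length_range``.
    """
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"invalid length_range {length_range}")
    for name, gc in (("gc_noncoding", gc_noncoding), ("gc_coding", gc_coding)):
        if not 0.0 < gc < 1.0:
            raise ConfigurationError(f"{name} must be in (0,1), got {gc}")
    orf_len = 3 * int(np.ceil(min_orf_bp / 3))
    if n_coding > 0 and lo < orf_len:
        raise ConfigurationError(
            f"coding sequences of length >= {lo} cannot carry a "
            f"{orf_len} bp ORF")
    rng = stage_rng(seed, "sequences")
    out: list[tuple[str, str]] = []
    for k in range(n_noncoding):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length, gc_noncoding)
        if longest_orf(seq) >= min_orf_bp:
            seq = _disrupt_orfs(seq, min_orf_bp, rng)
        out.append((f"nc_{k:05d}", seq))
    for k in range(n_coding):
        length = int(rng.integers(lo, hi + 1))
        offset = int(rng.integers(0, length - orf_len + 1))
        n_mid = orf_len // 3 - 2
        orf = "ATG" + "".join(_random_codon(rng, gc_coding)
                              for _ in range(n_mid))
        orf += ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        flank_left = _random_sequence(rng, offset, gc_coding)
        flank_right = _random_sequence(rng, length - offset - orf_len, gc_coding)
        out.append((f"cd_{k:05d}", flank_left + orf + flank_right))
    return out


def simulate_trait(
    matrix: ExpressionMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> pd.Series:
    """Per-individual trait: weighted log-expression of the trait genes
    plus Gaussian noise of sd ``trait_noise_sd``.

    Log-expression is ``log(FPKM + 0.01)`` (the pseudocount only matters
    for undetected values; planted trait genes are consistently
    detected), so every trait gene contributes on the same log scale.
    Deterministic under the config seed (its own sub-stream, so the
    trait can be regenerated without re-simulating expression).
    """
    if not truth.trait_genes:
        raise ConfigurationError("trait gene set is empty")
    missing = [g for g in truth.trait_genes if g not in matrix.values.index]
    if missing:
        raise ConfigurationError(f"trait gene not in matrix: {missing[0]!r}")
    rng = stage_rng(config.seed, "trait")
    log_expr = np.log(matrix.values.loc[list(truth.trait_genes)].to_numpy() + 0.01)
    loadings = np.array(list(truth.trait_genes.values()))
    trait = loadings @ log_expr
    trait = trait + config.trait_noise_sd * rng.standard_normal(trait.size)
    return pd.Series(trait, index=matrix.values.columns, name="trait_value")


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["env_names"] = list(d["env_names"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "env_names" in d:
        d["env_names"] = tuple(d["env_names"])
    try:
        cfg = SimulationConfig(**d)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    cfg.validate()
    return cfg
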