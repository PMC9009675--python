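"""Generative model for multi-trait multi-environment trial data.

Simulates the same structure the mixed-model stage fits: for trait *t* and
plot (genotype i, environment j, block k)

    y_tijk = mu_t + tau_tj + rho_jk + alpha_ti + (ge)_tij + eps_tijk

with genotype effects alpha ~ N(0, sigma2_g), interaction effects
(ge) ~ N(0, sigma2_ge) and residuals eps ~ N(0, sigma2_e).  Environment
(tau) and block-within-environment (rho) effects are fixed numbers supplied
in the configuration.  Genotype main effects are correlated across traits
through a genetic correlation matrix K (unit diagonal, PSD); interaction and
residual effects are drawn independently per trait.

Randomness protocol: the root seed feeds per-trait, per-term substreams
(numpy ``SeedSequence`` spawn keys), so appending a trait to a configuration
never perturbs the draws of existing traits, and the genotype-effect
correlation uses a lower-triangular square root of K so trait *t* depends
only on base streams 1..t.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import (
    WHEAT_TRAITS,
    wheat_genetic_summary,
    wheat_selection_summary,
)
from .trial import TraitSpec, TrialData

__all__ = [
    "TraitSim",
    "SimulationConfig",
    "TruthRecord",
    "simulate_met",
    "preset_wheat_drought",
]


@dataclass
class TraitSim:
    """Generative parameters for one trait.

    ``env_effects`` holds the fixed environment shifts tau_j (length e);
    ``block_effects`` the fixed block-within-environment shifts rho_jk
    (e rows, b columns).  Both default to zero.
    """

    name: str
    mean: float
    var_g: float
    var_ge: float
    var_e: float
    direction: str = "increase"
    units: str = ""
    env_effects: tuple[float, ...] | None = None
    block_effects: tuple[tuple[float, ...], ...] | None = None

    def spec(self) -> TraitSpec:
        return TraitSpec(name=self.name, direction=self.direction, units=self.units)


@dataclass
class SimulationConfig:
    g: int
    e: int
    b: int
    traits: list[TraitSim]
    correlation: np.ndarray | None = None  # p x p genetic correlation, None = identity
    seed: int = 0

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def validate(self) -> None:
        if min(self.g, self.e, self.b) < 1:
            raise ValueError("g, e, b must all be >= 1")
        for t in self.traits:
            for label, v in (("var_g", t.var_g), ("var_ge", t.var_ge), ("var_e", t.var_e)):
                if v < 0:
                    raise ValueError(f"trait {t.name!r}: {label} is negative ({v})")
            if t.env_effects is not None and len(t.env_effects) != self.e:
                raise ValueError(f"trait {t.name!r}: env_effects length != e")
            if t.block_effects is not None:
                rho = np.asarray(t.block_effects, dtype=float)
                if rho.shape != (self.e, self.b):
                    raise ValueError(f"trait {t.name!r}: block_effects shape != (e, b)")
        if self.correlation is not None:
            K = np.asarray(self.correlation, dtype=float)
            p = len(self.traits)
            if K.shape != (p, p):
                raise ValueError(f"correlation must be {p}x{p}")
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(K), 1.0, atol=1e-10):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(K).min() < -1e-10:
                raise ValueError("correlation matrix is not positive semi-definite")

    # --- YAML round trip ------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        doc = {
            "g": self.g,
            "e": self.e,
            "b": self.b,
            "seed": int(self.seed),
            "correlation": None
            if self.correlation is None
            else np.asarray(self.correlation, dtype=float).tolist(),
            "traits": [
                {
                    **{k: v for k, v in asdict(t).items() if v is not None},
                }
                for t in self.traits
            ],
        }
        Path(path).write_text(yaml.safe_dump(plain(doc), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text())
        traits = []
        for td in doc["traits"]:
            if "env_effects" in td and td["env_effects"] is not None:
                td["env_effects"] = tuple(td["env_effects"])
            if "block_effects" in td and td["block_effects"] is not None:
                td["block_effects"] = tuple(tuple(r) for r in td["block_effects"])
            traits.append(TraitSim(**td))
        corr = doc.get("correlation")
        return cls(
            g=int(doc["g"]),
            e=int(doc["e"]),
            b=int(doc["b"]),
            traits=traits,
            correlation=None if corr is None else np.asarray(corr, dtype=float),
            seed=int(doc.get("seed", 0)),
        )


@dataclass
class TruthRecord:
    """Drawn effects underlying a simulated trial, for recovery tests."""

    genotype_effects: pd.DataFrame  # g x p, index genotype ids
    ge_effects: pd.DataFrame  # long: genotype, environment, trait, effect
    config: SimulationConfig

    def write_csv(self, path: str | Path) -> None:
        self.ge_effects.to_csv(path, index=False)


def _lower_sqrt(K: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish square root of a PSD matrix.

    Cholesky when positive definite; otherwise an eigen square root with
    small negative eigenvalues clipped to zero.
    """
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(K)
        w = np.clip(w, 0.0, None)
        return V @ np.diag(np.sqrt(w))


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_met(config: SimulationConfig) -> tuple[TrialData, TruthRecord]:
    """Draw one trial from the generative model.

    Returns the phenotype table (one row per plot, one column per trait) and
    a :class:`TruthRecord` with every drawn random effect.  Identical
    configurations (including seed) give bit-identical output.
    """
    config.validate()
    g, e, b, p = config.g, config.e, config.b, len(config.traits)
    genotypes = [f"G{i + 1:02d}" for i in range(g)]
    environments = [f"E{j + 1}" for j in range(e)]
    blocks = [f"B{k + 1}" for k in range(b)]

    K = np.eye(p) if config.correlation is None else np.asarray(config.correlation, float)
    L = _lower_sqrt(K)

    # Genotype main effects: correlated across traits via base columns.
    base = np.column_stack(
        [_stream(config.seed, 1, t).standard_normal(g) for t in range(p)]
    )
    corr_base = base @ L.T  # column t mixes base columns <= t
    sd_g = np.array([np.sqrt(t.var_g) for t in config.traits])
    alpha = corr_base * sd_g  # g x p

    # Interaction and residual effects: independent per trait.
    ge = np.stack(
        [
            _stream(config.seed, 2, t).standard_normal((g, e))
            * np.sqrt(config.traits[t].var_ge)
            for t in range(p)
        ],
        axis=2,
    )  # g x e x p

    rows: dict[str, list] = {"genotype": [], "environment": [], "block": []}
    values = np.empty((g * e * b, p))
    idx = 0
    eps = np.stack(
        [
            _stream(config.seed, 3, t).standard_normal((g, e, b))
            * np.sqrt(config.traits[t].var_e)
            for t in range(p)
        ],
        axis=3,
    )
    for i in range(g):
        for j in range(e):
            for k in range(b):
                rows["genotype"].append(genotypes[i])
                rows["environment"].append(environments[j])
                rows["block"].append(blocks[k])
                for t, ts in enumerate(config.traits):
                    tau = 0.0 if ts.env_effects is None else ts.env_effects[j]
                    rho = 0.0 if ts.block_effects is None else ts.block_effects[j][k]
                    values[idx, t] = (
                        ts.mean + tau + rho + alpha[i, t] + ge[i, j, t] + eps[i, j, k, t]
                    )
                idx += 1

    table = pd.DataFrame(rows)
    for t, ts in enumerate(config.traits):
        table[ts.name] = values[:, t]
    data = TrialData(table=table, trait_specs=[t.spec() for t in config.traits])

    geno_df = pd.DataFrame(alpha, index=genotypes, columns=config.trait_names)
    geno_df.index.name = "genotype"
    ge_long = pd.DataFrame(
        [
            (genotypes[i], environments[j], config.traits[t].name, ge[i, j, t])
            for i in range(g)
            for j in range(e)
            for t in range(p)
        ],
        columns=["genotype", "environment", "trait", "effect"],
    )
    return data, TruthRecord(genotype_effects=geno_df, ge_effects=ge_long, config=config)


# Relative drought-vs-control shifts (fraction of the trait mean) used by the
# preset: yield and gas exchange fall under drought, osmolytes and
# antioxidants rise.  Encoded as centered fixed environment effects.
_DROUGHT_SHIFT = {
    "GY": -0.20,
    "HLW": -0.01,
    "AI": -0.30,
    "AF": -0.35,
    "gsI": -0.40,
    "gsF": -0.45,
    "pc": 1.30,
    "Na": 0.30,
    "K": 0.25,
    "TPC": 0.10,
    "ABTS": 0.10,
    "FRAP": 0.15,
}

# Factor groups of correlated traits (antioxidant/ion, conductance,
# osmotic/photosynthetic, agronomic) used to build the genetic correlation.
_TRAIT_GROUPS = [
    ("TPC", "ABTS", "K", "Na", "AI"),
    ("FRAP", "gsI", "gsF"),
    ("pc", "AF"),
    ("GY", "HLW"),
]


def _preset_correlation(names: Sequence[str]) -> np.ndarray:
    p = len(names)
    group_of = {t: gi for gi, grp in enumerate(_TRAIT_GROUPS) for t in grp}
    K = np.full((p, p), 0.1)
    for a in range(p):
        for c in range(p):
            if group_of.get(names[a]) == group_of.get(names[c]):
                K[a, c] = 0.6
        K[a, a] = 1.0
    # guard: clip tiny negative eigenvalues from rounding
    w = np.linalg.eigvalsh(K)
    if w.min() < 0:
        K = K + (1e-8 - w.min()) * np.eye(p)
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
    return K


def preset_wheat_drought(seed: int = 0) -> SimulationConfig:
    """Configuration emulating the reference wheat drought trial.

    18 genotypes x 2 environments (control, drought) x 3 blocks, 12 traits.
    Per-trait grand means come from the trial's published overall means;
    genotypic and residual variances are backed out from the published CVg%
    and CVr%, and the interaction variance from the published mean-basis
    heritability at e=2, b=3, so the simulated mean-basis heritabilities
    span the published ~0.03-0.85 range.  Selection directions match the
    trial (lower is better for Na, gsI, gsF).
    """
    gen = wheat_genetic_summary().set_index("trait")
    sel = wheat_selection_summary().set_index("trait")
    e, b = 2, 3
    traits: list[TraitSim] = []
    for name, (direction, units) in WHEAT_TRAITS.items():
        mu = float(sel.loc[name, "Xo"])
        h2, cvg, cvr = (float(gen.loc[name, c]) for c in ("h2", "cvg", "cvr"))
        var_g = (cvg / 100.0 * mu) ** 2
        var_e = (cvr / 100.0 * mu) ** 2
        # mean-basis h2 = vg / (vg + vge/e + ve/(e*b))  =>  solve for vge
        var_ge = max(e * (var_g / h2 - var_g - var_e / (e * b)), 0.0)
        shift = _DROUGHT_SHIFT[name] * mu
        # small fixed block gradients, a fraction of the residual sd
        sd_e = np.sqrt(var_e)
        block = tuple(
            tuple(0.3 * sd_e * (k - (b - 1) / 2) for k in range(b)) for _ in range(e)
        )
        traits.append(
            TraitSim(
                name=name,
                mean=mu,
                var_g=var_g,
                var_ge=var_ge,
                var_e=var_e,
                direction=direction,
                units=units,
                env_effects=(-shift / 2.0, shift / 2.0),
                block_effects=block,
            )
        )
    return SimulationConfig(
        g=18,
        e=e,
        b=b,
        traits=traits,
        correlation=_preset_correlation(list(WHEAT_TRAITS)),
        seed=seed,
    )
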