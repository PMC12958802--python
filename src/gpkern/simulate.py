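"""Synthetic multi-environment testcross data generator.

Emulates the statistical structure of a hybrid maize yield trial: a panel of
homozygous inbreds genotyped at biallelic SNPs, a testcross design pairing a
few testers with many candidate lines, hybrid genotypes formed as parental
averages, per-site soil covariates, per-site-year daily weather series, and
phenotypes decomposed into population mean plus additive, dominance,
epistatic, genotype-by-environment, environment-main and residual components
with user-specified variance fractions.

The generator is fully deterministic given the configuration seed, and the
realized variance of every simulated component is rescaled to match its
requested fraction exactly, so downstream variance-component estimates have a
known truth to be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    InvalidConfigError,
    InvalidDesignError,
    ShapeError,
)

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "CrossDesign",
    "TrialDesign",
    "PhenotypeTable",
    "simulate_inbred_panel",
    "make_testcross_design",
    "derive_hybrid_genotypes",
    "simulate_environments",
    "simulate_phenotypes",
    "split_train_test",
    "make_validation_splits",
]

_COMPONENTS = ("additive", "dominance", "epistatic", "gxe", "environment", "residual")

#: Affine map from the standardized simulation scale to a plausible grain
#: yield scale (bu/ac): yield = _YIELD_MEAN + _YIELD_SD * y_std.
_YIELD_MEAN = 150.0
_YIELD_SD = 25.0


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic trial dataset.

    ``variance_fractions`` gives the share of total phenotypic variance for
    each of: additive, dominance, epistatic, gxe, environment, residual.
    Fractions must sum to 1.
    """

    n_inbreds: int
    n_testers: int
    n_snps: int
    n_sites: int
    n_years: int
    variance_fractions: dict
    maf_range: tuple = (0.05, 0.5)
    n_soil_vars: int = 21
    n_weather_vars: int = 19
    day_range: tuple = (-75, 204)
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_inbreds": self.n_inbreds,
            "n_testers": self.n_testers,
            "n_snps": self.n_snps,
            "n_sites": self.n_sites,
            "n_years": self.n_years,
            "n_soil_vars": self.n_soil_vars,
            "n_weather_vars": self.n_weather_vars,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {value}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        unknown = set(self.variance_fractions) - set(_COMPONENTS)
        if unknown:
            raise InvalidConfigError(f"unknown variance components: {sorted(unknown)}")
        fracs = self.fractions()
        if any(v < 0 for v in fracs.values()):
            raise InvalidConfigError("variance fractions must be non-negative")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-12:
            raise InvalidConfigError(f"variance fractions must sum to 1, got {total}")
        if self.day_range[1] < self.day_range[0]:
            raise InvalidConfigError("day_range must be increasing")
        if self.n_testers >= self.n_inbreds:
            raise InvalidConfigError("n_testers must leave at least one line inbred")

    def fractions(self) -> dict:
        """Variance fractions with absent components filled in as 0."""
        return {c: float(self.variance_fractions.get(c, 0.0)) for c in _COMPONENTS}

    @property
    def n_days(self) -> int:
        return self.day_range[1] - self.day_range[0] + 1


@dataclass
class GenotypeMatrix:
    """Marker calls for a panel of individuals.

    ``calls`` holds counts of the reference allele in {0, 1, 2}; inbred
    panels contain only {0, 2}.  ``ref_allele_freqs`` are the per-locus
    reference-allele frequencies; when not supplied they are computed from
    the panel itself.
    """

    calls: np.ndarray
    individual_ids: list
    locus_ids: list
    ref_allele_freqs: np.ndarray = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ShapeError("calls shape does not match id lists")
        if self.ref_allele_freqs is None:
            self.ref_allele_freqs = self.calls.mean(axis=0) / 2.0
        else:
            self.ref_allele_freqs = np.asarray(self.ref_allele_freqs, dtype=float)
            if self.ref_allele_freqs.shape != (len(self.locus_ids),):
                raise ShapeError("ref_allele_freqs length does not match loci")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.ref_allele_freqs
        return np.minimum(p, 1.0 - p)


@dataclass
class CrossDesign:
    """Binary incidence of hybrids onto their two inbred parents.

    Every row of ``M`` has exactly two 1 entries (tester and line).
    """

    M: np.ndarray
    hybrid_ids: list
    parent_pairs: list  # list of (tester_id, line_id)
    inbred_ids: list  # column labels of M

    def __post_init__(self):
        self.M = np.asarray(self.M)
        if not np.all(self.M.sum(axis=1) == 2):
            raise InvalidDesignError("every hybrid must link exactly two parents")

    @property
    def n_hybrids(self) -> int:
        return self.M.shape[0]


@dataclass
class TrialDesign:
    """Site-year structure: per-site soil vectors and per-site-year weather.

    ``weather`` has shape (n_site_years, n_variables, n_days).  Soil is a
    site-level table replicated across years of the same site.
    """

    site_years: list
    sites: list  # site of each site_year, aligned
    soil: pd.DataFrame  # index: site, columns: soil variables
    weather: np.ndarray
    weather_vars: list
    days: np.ndarray

    def soil_by_site_year(self) -> pd.DataFrame:
        """Soil table expanded to one row per site-year."""
        out = self.soil.loc[self.sites].copy()
        out.index = pd.Index(self.site_years, name="site_year")
        return out


@dataclass
class PhenotypeTable:
    """Yield records keyed by (hybrid, site-year) with partition flags.

    ``data`` columns: hybrid_id, site_year, yield, partition ('train'/'test'
    or None before splitting), y_std after splitting.  ``components`` stores
    the true simulated components per record (standardized scale) for
    variance-decomposition checks.
    """

    data: pd.DataFrame
    train_mean: float = None
    train_sd: float = None
    components: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def train_mask(self) -> np.ndarray:
        return (self.data["partition"] == "train").to_numpy()

    def standardize(self) -> "PhenotypeTable":
        """Center/scale yields by the training-partition mean and sd."""
        if "partition" not in self.data or self.data["partition"].isna().all():
            raise InvalidConfigError("standardize requires a train/test partition")
        train_y = self.data.loc[self.data["partition"] == "train", "yield"]
        mean, sd = float(train_y.mean()), float(train_y.std(ddof=0))
        out = self.data.copy()
        out["y_std"] = (out["yield"] - mean) / sd
        return PhenotypeTable(out, train_mean=mean, train_sd=sd, components=self.components)

    def destandardize(self, values: np.ndarray) -> np.ndarray:
        if self.train_mean is None:
            raise InvalidConfigError("no stored train statistics")
        return np.asarray(values) * self.train_sd + self.train_mean


# ---------------------------------------------------------------------------
# genotypes and crosses


def simulate_inbred_panel(config: SimConfig, rng=None) -> GenotypeMatrix:
    """Simulate a homozygous inbred panel with calls in {0, 2}.

    Per-locus reference-allele frequencies are drawn uniformly on
    ``maf_range`` and loci whose *realized* minor-allele frequency falls
    below the lower bound (including monomorphic loci) are redrawn, so the
    returned panel has no locus rarer than requested.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lo, hi = config.maf_range
    n, p = config.n_inbreds, config.n_snps
    calls = np.empty((n, p), dtype=np.int8)
    pending = np.arange(p)
    for _ in range(1000):
        freqs = rng.uniform(lo, hi, size=pending.size)
        draw = (rng.random((n, pending.size)) < freqs).astype(np.int8) * 2
        calls[:, pending] = draw
        realized = calls[:, pending].mean(axis=0) / 2.0
        maf = np.minimum(realized, 1.0 - realized)
        bad = maf < lo
        pending = pending[bad]
        if pending.size == 0:
            break
    else:  # pragma: no cover - pathological maf_range/sample-size combinations
        raise InvalidConfigError("could not realize requested MAF spectrum")
    ids = [f"I{i:04d}" for i in range(n)]
    loci = [f"snp{j:05d}" for j in range(p)]
    return GenotypeMatrix(calls=calls, individual_ids=ids, locus_ids=loci)


def make_testcross_design(
    n_testers: int,
    n_lines: int,
    crosses_per_line: int,
    seed: int = 0,
    tester_ids: list = None,
    line_ids: list = None,
) -> CrossDesign:
    """Pair each candidate line with ``crosses_per_line`` random testers.

    Testers occupy the first ``n_testers`` columns of the incidence matrix
    unless explicit id lists are given; tester and line sets must not
    overlap.
    """
    if n_testers < 1 or n_lines < 1 or crosses_per_line < 1:
        raise InvalidDesignError("counts must be >= 1")
    if crosses_per_line > n_testers:
        raise InvalidDesignError("crosses_per_line cannot exceed n_testers")
    if tester_ids is None:
        tester_ids = [f"I{i:04d}" for i in range(n_testers)]
    if line_ids is None:
        line_ids = [f"I{i:04d}" for i in range(n_testers, n_testers + n_lines)]
    if set(tester_ids) & set(line_ids):
        raise InvalidDesignError("tester set overlaps line set")
    if len(tester_ids) != n_testers or len(line_ids) != n_lines:
        raise InvalidDesignError("id lists do not match requested counts")

    rng = np.random.default_rng(seed)
    inbred_ids = list(tester_ids) + list(line_ids)
    col = {iid: j for j, iid in enumerate(inbred_ids)}
    rows, hybrid_ids, pairs = [], [], []
    for line in line_ids:
        chosen = rng.choice(n_testers, size=crosses_per_line, replace=False)
        for t in np.sort(chosen):
            tester = tester_ids[t]
            row = np.zeros(len(inbred_ids), dtype=np.int8)
            row[col[tester]] = 1
            row[col[line]] = 1
            rows.append(row)
            hybrid_ids.append(f"{tester}x{line}")
            pairs.append((tester, line))
    return CrossDesign(
        M=np.array(rows), hybrid_ids=hybrid_ids, parent_pairs=pairs, inbred_ids=inbred_ids
    )


def derive_hybrid_genotypes(X: GenotypeMatrix, design: CrossDesign) -> GenotypeMatrix:
    """Hybrid marker calls as the average of the two parents: H = (1/2) M X."""
    if design.M.shape[1] != X.n_individuals:
        raise ShapeError(
            f"design has {design.M.shape[1]} parents but panel has {X.n_individuals}"
        )
    if list(design.inbred_ids) != list(X.individual_ids):
        raise AlignmentError("design parent ids do not match panel individual ids")
    calls = 0.5 * (design.M @ X.calls.astype(float))
    return GenotypeMatrix(
        calls=calls, individual_ids=list(design.hybrid_ids), locus_ids=list(X.locus_ids)
    )


# ---------------------------------------------------------------------------
# environments


def simulate_environments(config: SimConfig, rng=None) -> TrialDesign:
    """Simulate per-site soil vectors and per-site-year daily weather grids.

    Soil is site-level (years of a site share the vector exactly).  Weather
    for each (site-year, variable) is a smooth seasonal signal with
    site-specific amplitude/phase, a year-specific shift, and daily noise.
    """
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    sites = [f"S{i:02d}" for i in range(config.n_sites)]
    site_years, sy_sites = [], []
    for s in sites:
        for y in range(config.n_years):
            site_years.append(f"{s}_Y{y}")
            sy_sites.append(s)

    soil_cols = [f"soil{v:02d}" for v in range(config.n_soil_vars)]
    soil = pd.DataFrame(
        rng.normal(size=(config.n_sites, config.n_soil_vars)),
        index=pd.Index(sites, name="site"),
        columns=soil_cols,
    )

    days = np.arange(config.day_range[0], config.day_range[1] + 1)
    t = (days - days[0]) / max(len(days) - 1, 1)
    n_sy, n_v = len(site_years), config.n_weather_vars
    # site-level seasonal parameters shared across years, year shifts on top
    amp = 1.0 + 0.5 * rng.normal(size=(config.n_sites, n_v))
    phase = rng.uniform(0, 2 * np.pi, size=(config.n_sites, n_v))
    level = rng.normal(size=(config.n_sites, n_v))
    year_shift = rng.normal(scale=0.5, size=(n_sy, n_v))
    weather = np.empty((n_sy, n_v, len(days)))
    site_index = {s: i for i, s in enumerate(sites)}
    for k, (sy, s) in enumerate(zip(site_years, sy_sites)):
        i = site_index[s]
        seasonal = amp[i][:, None] * np.sin(2 * np.pi * t[None, :] + phase[i][:, None])
        noise = rng.normal(scale=0.3, size=(n_v, len(days)))
        weather[k] = level[i][:, None] + year_shift[k][:, None] + seasonal + noise
    weather_vars = [f"wx{v:02d}" for v in range(n_v)]
    return TrialDesign(
        site_years=site_years,
        sites=sy_sites,
        soil=soil,
        weather=weather,
        weather_vars=weather_vars,
        days=days,
    )


# ---------------------------------------------------------------------------
# phenotypes


def _scale_to_fraction(values: np.ndarray, fraction: float) -> np.ndarray:
    """Rescale a component so its realized variance equals ``fraction``."""
    if fraction <= 0:
        return np.zeros_like(values)
    v = values.var()
    if v <= 0:
        raise InvalidConfigError(
            "a non-zero variance fraction was requested for a degenerate component"
        )
    return (values - values.mean()) * np.sqrt(fraction / v)


def simulate_phenotypes(
    hybrids: GenotypeMatrix,
    trial: TrialDesign,
    config: SimConfig,
    rng=None,
) -> PhenotypeTable:
    """Simulate yields y = mu + a + d + i + gxe + e + eps on the full grid.

    Every hybrid is observed in every site-year.  Components (standardized
    scale):

    * a — additive-coded genotypes times iid normal effects;
    * d — dominance-coded genotypes times iid normal effects;
    * i — additive-by-additive products at random locus pairs times effects;
    * e — site-year main effect built from soil and season-average weather;
    * gxe — rank-1 interaction: per-hybrid additive score times a
      per-environment index;
    * eps — iid residual noise.

    Each component is centered and rescaled so its realized variance equals
    the requested fraction exactly; yields are affine-mapped to a plausible
    bu/ac range, and true components are stored for recovery checks.
    """
    from .codings import additive_code, dominance_code

    rng = np.random.default_rng(config.seed + 2 if rng is None else rng)
    fr = config.fractions()
    genetic = fr["additive"] + fr["dominance"] + fr["epistatic"] + fr["gxe"]
    if genetic <= 0 and fr["environment"] <= 0 and fr["residual"] <= 0:
        raise InvalidConfigError("all variance fractions are zero")

    m, p = hybrids.n_individuals, hybrids.n_loci
    freqs = np.clip(hybrids.ref_allele_freqs, 1e-6, 1 - 1e-6)
    A = additive_code(hybrids, freqs, allow_monomorphic=True).values
    D = dominance_code(hybrids, freqs, allow_monomorphic=True).values

    a_h = A @ rng.normal(size=p) / np.sqrt(p)
    d_h = D @ rng.normal(size=p) / np.sqrt(p)
    n_pairs = min(2 * p, 500)
    ii = rng.integers(0, p, size=n_pairs)
    jj = rng.integers(0, p, size=n_pairs)
    i_h = (A[:, ii] * A[:, jj]) @ rng.normal(size=n_pairs) / np.sqrt(n_pairs)
    gxe_score = A @ rng.normal(size=p) / np.sqrt(p)

    sy = trial.site_years
    soil_sy = trial.soil_by_site_year().to_numpy()
    wx_mean = trial.weather.mean(axis=2)  # season-average weather per site-year
    e_env = soil_sy @ rng.normal(size=soil_sy.shape[1]) + wx_mean @ rng.normal(
        size=wx_mean.shape[1]
    )
    env_index = soil_sy @ rng.normal(size=soil_sy.shape[1]) + wx_mean @ rng.normal(
        size=wx_mean.shape[1]
    )
    env_index = (env_index - env_index.mean()) / max(env_index.std(), 1e-12)

    n_env = len(sy)
    hyb_idx = np.repeat(np.arange(m), n_env)
    env_idx = np.tile(np.arange(n_env), m)
    comp = {
        "additive": a_h[hyb_idx],
        "dominance": d_h[hyb_idx],
        "epistatic": i_h[hyb_idx],
        "environment": e_env[env_idx],
        "gxe": (gxe_score - gxe_score.mean())[hyb_idx] * env_index[env_idx],
        "residual": rng.normal(size=m * n_env),
    }
    comp = {k: _scale_to_fraction(v, fr[k]) for k, v in comp.items()}
    y_std = sum(comp.values())
    data = pd.DataFrame(
        {
            "hybrid_id": np.asarray(hybrids.individual_ids)[hyb_idx],
            "site_year": np.asarray(sy)[env_idx],
            "yield": _YIELD_MEAN + _YIELD_SD * y_std,
            "partition": pd.Series([None] * (m * n_env), dtype=object),
        }
    )
    return PhenotypeTable(data=data, components=comp)


# ---------------------------------------------------------------------------
# splitting


def split_train_test(
    table: PhenotypeTable,
    test_site_year_count: int = 16,
    cap: int = 265,
    seed: int = 0,
) -> PhenotypeTable:
    """Hold out whole site-years for testing and cap records per site-year.

    Held-out site-years go entirely to the test partition (tested genotypes
    in untested environments); any site-year with more than ``cap`` records
    is down-sampled to ``cap``.  Yields are then standardized by the
    training-partition mean and sd.
    """
    if cap is not None and cap < 1:
        raise InvalidConfigError("cap must be >= 1 (or None for no cap)")
    site_years = sorted(table.data["site_year"].unique())
    if test_site_year_count >= len(site_years):
        raise InvalidConfigError("test_site_year_count must be < number of site-years")
    rng = np.random.default_rng(seed)
    test_sy = set(rng.choice(site_years, size=test_site_year_count, replace=False))

    keep = []
    comp_keep = []
    for sy_name, group in table.data.groupby("site_year", sort=True):
        idx = group.index.to_numpy()
        if cap is not None and len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
            idx.sort()
        keep.append(idx)
    keep = np.concatenate(keep)
    keep.sort()
    data = table.data.loc[keep].reset_index(drop=True)
    data["partition"] = np.where(data["site_year"].isin(test_sy), "test", "train")
    components = {k: np.asarray(v)[keep] for k, v in table.components.items()}
    out = PhenotypeTable(data=data, components=components)
    return out.standardize()


def make_validation_splits(
    table: PhenotypeTable,
    n_splits: int = 10,
    n_env_per_split: int = 16,
    seed: int = 0,
) -> list:
    """Sample site-year-based train/validation partitions of the training set.

    Each split holds out all records of ``n_env_per_split`` sampled training
    site-years as validation; the remainder stays in that split's training
    portion.  Returns a list of dicts with boolean index arrays over
    ``table.data`` rows and the sampled site-years.
    """
    train = table.data["partition"] == "train"
    train_sy = sorted(table.data.loc[train, "site_year"].unique())
    if n_env_per_split >= len(train_sy):
        raise InvalidConfigError("n_env_per_split must be < number of training site-years")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        val_sy = set(rng.choice(train_sy, size=n_env_per_split, replace=False))
        is_val = train & table.data["site_year"].isin(val_sy)
        splits.append(
            {
                "val_site_years": sorted(val_sy),
                "train_index": (train & ~is_val).to_numpy(),
                "val_index": is_val.to_numpy(),
            }
        )
    return splits
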