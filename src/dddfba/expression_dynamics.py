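"""mRNA/protein balance dynamics and enzyme-capacity flux bounds.

For each *balanced* reaction i (a reaction whose enzyme expression is
simulated explicitly) the model is a pair of linear ODEs:

    d[mRNA_i]/dt = s_b,i + R_i(t) * s_a,i - (mu + gamma_i) * [mRNA_i]
    d[P_i]/dt    = s_P,i * [mRNA_i] - mu * [P_i]

with a demand-driven regulatory signal

    R_i(t) = 1  if  j_i(t) >= theta * b_i(t),  else 0

and an enzyme-capacity upper bound on the flux

    b_i(t) = kcat_i * [P_i](t).

The mRNA equation mixes constitutive (basal) transcription s_b, an
activated rate s_a switched by demand, active degradation gamma and
dilution by growth; the protein equation has synthesis proportional to the
mRNA level (rate s_P = tau / Lambda_app, inversely proportional to the
apparent gene length because ribosomes traverse the transcript at finite
speed) and dilution only — protein degradation is negligible on the
time scale of interest.

Units follow the measurement conventions of the data the model was built
for and are deliberately mixed: mRNA is in RPKM with transcription rates
per *minute*; protein is in mmol/gDCW with synthesis per *hour*; growth mu
is per hour and converted where needed.  Within one quasi-steady-state step
the regulatory signal and (for the protein update) the mRNA level are held
constant, which makes both updates exact exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import math

import numpy as np
import pandas as pd
import yaml

from .model_io import DEFAULT_RIBOSOME_SPACING_BP, apparent_gene_length

#: Default translation constant tau (bp * mmol / (h * RPKM * gDCW)).
DEFAULT_TAU = 0.6

#: Default regulatory threshold theta (fraction of the bound that counts
#: as demand; most enzymes run more than half-saturated, hence 0.6).
DEFAULT_THETA = 0.6

#: Anaerobic growth rate used for basal steady states (h^-1).
DEFAULT_MU_ANAEROBIC = 0.26


@dataclass
class EnzymeKinetics:
    """Per-reaction expression and capacity parameters.

    Attributes
    ----------
    reaction:
        Reaction id the bound applies to.
    gene:
        Gene of the largest subunit (rate-limiting for expression).
    gene_length_bp:
        Raw coding length of that gene (bp).
    copies:
        Copies of the largest subunit in the holoenzyme; >1 switches the
        apparent-gene-length correction on.
    s_b, s_a:
        Basal and activated transcription rates (RPKM/min).
    gamma:
        mRNA degradation rate (1/min).
    kcat:
        Turnover number.  Used numerically as mmol flux per mmol enzyme per
        hour (see :func:`flux_bound`).
    s_p:
        Optional explicit protein synthesis rate (mmol h^-1 RPKM^-1
        gDCW^-1); when absent it is derived as tau / apparent length.
    spacing_bp:
        Interribosomal distance used in the apparent-length correction.
    """

    reaction: str
    gene: str
    gene_length_bp: int
    s_b: float
    s_a: float
    gamma: float
    kcat: float
    copies: int = 1
    s_p: float | None = None
    spacing_bp: int = DEFAULT_RIBOSOME_SPACING_BP

    def __post_init__(self) -> None:
        if min(self.s_b, self.s_a, self.gamma, self.kcat) < 0:
            raise ValueError(f"{self.reaction}: rates must be non-negative")
        if self.gene_length_bp < 1:
            raise ValueError(f"{self.reaction}: gene length must be >= 1 bp")

    @property
    def apparent_length_bp(self) -> int:
        return apparent_gene_length(self.gene_length_bp, self.copies,
                                    self.spacing_bp)

    def synthesis_rate(self, tau: float = DEFAULT_TAU) -> float:
        """Protein synthesis rate s_P = tau / Lambda_app, or the explicit value."""
        if self.s_p is not None:
            return self.s_p
        return tau / self.apparent_length_bp


@dataclass
class RegulatoryConfig:
    """Global knobs of the expression/regulation layer."""

    theta: float = DEFAULT_THETA
    tau: float = DEFAULT_TAU
    spacing_bp: int = DEFAULT_RIBOSOME_SPACING_BP
    dt_min: float = 0.5
    mu_anaerobic: float = DEFAULT_MU_ANAEROBIC
    #: multiply kcat by this factor when computing bounds (unit convention knob)
    kcat_unit_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta <= 1.0:
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if self.dt_min <= 0:
            raise ValueError(f"dt_min must be positive, got {self.dt_min}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegulatoryConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)


def regulatory_signal(j: float, b: float, theta: float = DEFAULT_THETA) -> int:
    """Demand signal: 1 when the flux uses at least a fraction theta of its bound.

    The comparison is inclusive (j >= theta*b), so a flux sitting exactly at
    the threshold — in particular a flux pinned at its bound — counts as
    demand.  Inputs are magnitudes; pass |j| for reversible reactions.
    """
    if j < 0 or b < 0:
        raise ValueError("regulatory_signal expects non-negative magnitudes")
    return 1 if j >= theta * b else 0


def mrna_step(m: float, R: int, kin: EnzymeKinetics, mu_per_min: float,
              dt_min: float) -> float:
    """Advance the mRNA balance one step (exact linear-ODE update).

    With synthesis s = s_b + R*s_a and decay k = mu + gamma (both per
    minute, R constant over the step), the update is

        m' = m_ss + (m - m_ss) * exp(-k dt),   m_ss = s / k,

    degenerating to linear growth m' = m + s*dt when k = 0.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    s = kin.s_b + R * kin.s_a
    k = mu_per_min + kin.gamma
    if k == 0.0:
        return m + s * dt_min
    m_ss = s / k
    return m_ss + (m - m_ss) * math.exp(-k * dt_min)


def protein_step(p: float, m: float, kin: EnzymeKinetics, mu_per_h: float,
                 dt_h: float, tau: float = DEFAULT_TAU) -> float:
    """Advance the protein balance one step with the mRNA held constant.

    Exact update of dp/dt = s_P*m - mu*p:
        p' = p_ss + (p - p_ss) * exp(-mu dt),   p_ss = s_P*m/mu,
    with the mu = 0 branch p' = p + s_P*m*dt.
    """
    if dt_h <= 0:
        raise ValueError("dt_h must be positive")
    s = kin.synthesis_rate(tau) * m
    if mu_per_h == 0.0:
        return p + s * dt_h
    p_ss = s / mu_per_h
    return p_ss + (p - p_ss) * math.exp(-mu_per_h * dt_h)


def flux_bound(kcat: float, p: float, unit_factor: float = 1.0) -> float:
    """Enzyme-capacity bound b = kcat * [P].

    The turnover number is applied as a plain numeric factor on the protein
    level in mmol/gDCW, yielding a bound in mmol h^-1 gDCW^-1; converting
    kcat from s^-1 to h^-1 (x3600) would put the bounds three to four
    orders of magnitude above any realistic flux, so no time-unit
    conversion is applied by default.  ``unit_factor`` exposes the scaling
    as a configuration knob.
    """
    if kcat < 0 or p < 0:
        raise ValueError("kcat and protein level must be non-negative")
    return kcat * unit_factor * p


def steady_state_expression(kin: EnzymeKinetics, mu_per_h: float, R: int = 0,
                            tau: float = DEFAULT_TAU) -> tuple[float, float]:
    """Equilibrium (mRNA, protein) of the balance ODEs at fixed R and mu.

        mRNA_ss    = (s_b + R*s_a) / (mu + gamma)     [per-minute rates]
        protein_ss = s_P * mRNA_ss / mu               [per-hour rates]

    Used as the t = 0 initial condition of an anaerobic culture with all
    demand signals off (R = 0).
    """
    if mu_per_h <= 0:
        raise ValueError("protein steady state requires mu > 0")
    mu_per_min = mu_per_h / 60.0
    k = mu_per_min + kin.gamma
    if k <= 0:
        raise ValueError("mu + gamma must be positive")
    m_ss = (kin.s_b + R * kin.s_a) / k
    p_ss = kin.synthesis_rate(tau) * m_ss / mu_per_h
    return m_ss, p_ss


# ---------------------------------------------------------------------------
# Kinetics table I/O (layout of a per-enzyme parameter table)

_KINETICS_COLUMNS = ["reaction", "gene", "gene_length_bp", "copies",
                     "s_b", "s_a", "gamma", "kcat"]


def read_kinetics_table(path: str | Path) -> list[EnzymeKinetics]:
    """Read per-enzyme kinetics from TSV.

    Required columns: reaction, gene, gene_length_bp, copies, s_b, s_a,
    gamma, kcat; optional: s_p (explicit synthesis-rate override).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_KINETICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: kinetics table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        s_p = getattr(row, "s_p", None)
        if s_p is not None and pd.isna(s_p):
            s_p = None
        out.append(EnzymeKinetics(
            reaction=row.reaction, gene=row.gene,
            gene_length_bp=int(row.gene_length_bp), copies=int(row.copies),
            s_b=float(row.s_b), s_a=float(row.s_a), gamma=float(row.gamma),
            kcat=float(row.kcat), s_p=None if s_p is None else float(s_p),
        ))
    return out


def write_kinetics_table(kinetics: list[EnzymeKinetics], path: str | Path) -> None:
    rows = [{
        "reaction": k.reaction, "gene": k.gene,
        "gene_length_bp": k.gene_length_bp, "copies": k.copies,
        "s_b": k.s_b, "s_a": k.s_a, "gamma": k.gamma, "kcat": k.kcat,
        "s_p": np.nan if k.s_p is None else k.s_p,
    } for k in kinetics]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
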