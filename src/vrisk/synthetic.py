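"""Two-site synthetic EHR corpus generator with known ground truth.

Emulates the statistical shape of a psychiatric-admissions register — patients
with repeat admissions, lognormal lengths of stay and note volumes, a violent
outcome with single-digit percentage prevalence, violent-incident timing
concentrated early in the admission — while planting a controllable term-level
signal in the note text so that every downstream stage (labeling, embedding,
classification, transfer, term screening) can be tested against ground truth.

Notes are synthetic token streams, not natural language: only the
distributional structure (vocabulary frequencies, outcome-dependent occurrence
of signal terms, document lengths) matters to the pipeline. Each signal term
occurs in a predictor-window note with probability
``sigmoid(logit(base) + log_odds * outcome)``; a negative ``log_odds`` makes a
term protective. Cross-site vocabulary drift is modelled by replacing a signal
term with a site-local synonym with probability ``site_shift``, mimicking how
two hospitals describe the same behaviour with different words.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

EPOCH = pd.Timestamp("2013-01-01")
DAY = pd.Timedelta(days=1)

VIOLENT_CATEGORIES = ("violence_verbal", "violence_physical")
NONVIOLENT_CATEGORIES = ("self_harm", "substance_use", "sexual_intimidation", "vandalism")


@dataclass
class SiteProfile:
    """Parameters of one synthetic site.

    The headline fields mirror a descriptive-statistics table: number of
    unique patients, mean admissions per patient, outcome prevalence per
    admission, lognormal length-of-stay and note-length (words in the
    predictor window) parameters, the fractions of all incidents falling in
    the first 24 hours / first 4 weeks, and a diagnosis mixture. The
    remaining fields are generator knobs documented in docs/methods.md.
    """

    site_id: str
    n_patients: int
    admission_rate: float
    prevalence: float
    los_log_mean: float
    los_log_sd: float
    notelen_log_mean: float
    notelen_log_sd: float
    frac_incidents_first4w: float
    frac_incidents_first24h: float
    diagnosis_mixture: dict[str, float]
    vocab_size: int = 5000
    signal_terms: list[tuple[str, float]] = field(default_factory=list)
    site_shift: float = 0.0
    # generator knobs beyond the headline statistics
    incidents_per_positive: float = 3.3
    nonviolent_incident_rate: float = 0.08
    soas_mode: int = 12
    n_underdocumented: int = 0
    signal_base_prob: float = 0.05
    study_days: float = 2000.0
    notes_in_window_mean: float = 6.0
    notes_post24h_mean: float = 4.0
    n_wards: int = 4

    def validate(self) -> None:
        """Raise ValueError naming the first violated invariant."""
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.admission_rate < 1:
            raise ValueError("admission_rate must be >= 1 (mean admissions per patient)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for name in ("los_log_sd", "notelen_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        f4, f24 = self.frac_incidents_first4w, self.frac_incidents_first24h
        if not 0 <= f4 <= 1 or not 0 <= f24 <= 1:
            raise ValueError("incident-timing fractions must lie in [0, 1]")
        if f24 > f4:
            raise ValueError("frac_incidents_first24h must not exceed frac_incidents_first4w")
        total = sum(self.diagnosis_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"diagnosis_mixture must sum to 1 (got {total!r})")
        if not 0 <= self.site_shift <= 1:
            raise ValueError("site_shift must lie in [0, 1]")
        if not 0 < self.signal_base_prob < 1:
            raise ValueError("signal_base_prob must lie in (0, 1)")
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")
        if self.n_underdocumented < 0:
            raise ValueError("n_underdocumented must be >= 0")


@dataclass
class GroundTruth:
    """Per-admission truth: outcome label, latent risk, planted terms."""

    outcome: dict[str, int]
    latent_risk: dict[str, float]
    signal_terms: list[tuple[str, float]]

    def frame(self) -> pd.DataFrame:
        ids = list(self.outcome)
        return pd.DataFrame(
            {
                "admission_id": ids,
                "outcome": [self.outcome[i] for i in ids],
                "latent_risk": [self.latent_risk[i] for i in ids],
            }
        )


@dataclass
class SiteCorpus:
    admissions: pd.DataFrame
    notes: pd.DataFrame
    incidents: pd.DataFrame
    truth: GroundTruth
    profile: SiteProfile
    seed: int


def _zipf_probs(v: int) -> np.ndarray:
    p = 1.0 / (np.arange(v) + 10.0)
    return p / p.sum()


def generate_site(profile: SiteProfile, seed: int) -> SiteCorpus:
    """Generate one site's admissions, notes, incidents and ground truth.

    Deterministic for a fixed (profile, seed): generating twice yields
    byte-identical tables.
    """
    profile.validate()
    rng = np.random.default_rng(seed)

    # --- patients and admissions -------------------------------------------
    n_per_patient = 1 + rng.poisson(profile.admission_rate - 1.0, profile.n_patients)
    n_adm = int(n_per_patient.sum())
    patient_idx = np.repeat(np.arange(profile.n_patients), n_per_patient)
    patient_ids = np.array([f"{profile.site_id}-P{i:05d}" for i in range(profile.n_patients)])
    admission_ids = np.array([f"{profile.site_id}-A{i:06d}" for i in range(n_adm)])

    # outcome via a latent Gaussian risk score: marginal is exactly Bernoulli(prevalence)
    latent = rng.standard_normal(n_adm)
    outcome = (latent > norm.ppf(1.0 - profile.prevalence)).astype(int)

    los = rng.lognormal(profile.los_log_mean, profile.los_log_sd, n_adm)
    los = np.maximum(los, 0.25)
    # a positive admission needs a nonempty outcome window (24 h .. min(28 d, end))
    short_pos = (outcome == 1) & (los <= 1.1)
    while short_pos.any():
        los[short_pos] = np.maximum(
            rng.lognormal(profile.los_log_mean, profile.los_log_sd, int(short_pos.sum())), 0.25
        )
        short_pos = (outcome == 1) & (los <= 1.1)

    # admission start times: first start uniform over the study window, later
    # admissions of the same patient start >= 15 d after the previous discharge
    # so that distinct admissions stay distinct under the 14-day merge rule.
    start_d = np.empty(n_adm)
    pos = 0
    for count in n_per_patient:
        start_d[pos] = rng.uniform(0.0, profile.study_days)
        for j in range(pos + 1, pos + count):
            gap = 15.0 + rng.exponential(45.0)
            start_d[j] = start_d[j - 1] + los[j - 1] + gap
        pos += count

    diagnoses = list(profile.diagnosis_mixture)
    diag_p = np.array([profile.diagnosis_mixture[d] for d in diagnoses])
    diagnosis = rng.choice(diagnoses, size=n_adm, p=diag_p / diag_p.sum())
    ward = np.array(
        [f"{profile.site_id}-W{w}" for w in rng.integers(1, profile.n_wards + 1, n_adm)]
    )

    starts = EPOCH + pd.to_timedelta(np.round(start_d * 24 * 60) , unit="m")
    ends = starts + pd.to_timedelta(np.round(los * 24 * 60), unit="m")
    admissions = pd.DataFrame(
        {
            "admission_id": admission_ids,
            "patient_id": patient_ids[patient_idx],
            "start": starts,
            "end": ends,
            "ward": ward,
            "diagnosis": diagnosis,
            "site": profile.site_id,
        }
    )

    # --- notes --------------------------------------------------------------
    vocab = np.array([f"w{i:05d}" for i in range(profile.vocab_size)])
    bg_p = _zipf_probs(profile.vocab_size)
    sig_terms = [t for t, _ in profile.signal_terms]
    sig_logodds = np.array([d for _, d in profile.signal_terms])
    base_logit = logit(profile.signal_base_prob)

    under = set(
        rng.choice(n_adm, size=min(profile.n_underdocumented, n_adm), replace=False).tolist()
    )

    note_adm: list[str] = []
    note_role: list[str] = []
    note_ts: list[pd.Timestamp] = []
    note_text: list[str] = []

    for i in range(n_adm):
        start = starts[i]
        y = outcome[i]

        # predictor-window notes: [start - 28 d, start + 24 h]
        n_in = 1 + rng.poisson(max(profile.notes_in_window_mean - 1.0, 0.0))
        total_words = max(20, int(round(rng.lognormal(profile.notelen_log_mean, profile.notelen_log_sd))))
        counts = rng.multinomial(max(total_words - n_in, 0), np.full(n_in, 1.0 / n_in)) + 1
        offsets = np.sort(rng.uniform(-28.0, 1.0, n_in))
        if sig_terms:
            p_occ = expit(base_logit + sig_logodds * y)
        for j in range(n_in):
            # list, not ndarray: fixed-width string dtype would truncate
            # signal terms on insertion
            toks = list(vocab[rng.choice(profile.vocab_size, size=counts[j], p=bg_p)])
            if sig_terms:
                occur = rng.random(len(sig_terms)) < p_occ
                for k in np.flatnonzero(occur):
                    copies = 1 + rng.poisson(0.5)
                    for where in rng.integers(0, len(toks) + 1, copies):
                        toks.insert(int(where), sig_terms[k])
            note_adm.append(admission_ids[i])
            note_role.append("psychiatrist" if rng.random() < 0.3 else "nurse")
            note_ts.append(start + offsets[j] * DAY)
            note_text.append(" ".join(toks))

        # post-24h documentation (outcome-period notes; drive the <100-word rule)
        n_post = 1 + rng.poisson(max(profile.notes_post24h_mean - 1.0, 0.0))
        total_post = 40 if i in under else 110 + rng.poisson(150)
        pcounts = rng.multinomial(max(total_post - n_post, 0), np.full(n_post, 1.0 / n_post)) + 1
        span = max(los[i] - 1.0, 1.0)
        poffsets = np.sort(1.0 + rng.uniform(0.0, span, n_post) * (1.0 - 1e-6) + 1e-4)
        for j in range(n_post):
            toks = vocab[rng.choice(profile.vocab_size, size=pcounts[j], p=bg_p)]
            note_adm.append(admission_ids[i])
            note_role.append("psychiatrist" if rng.random() < 0.3 else "nurse")
            note_ts.append(start + poffsets[j] * DAY)
            note_text.append(" ".join(toks))

        # occasional stale note before the predictor window
        if rng.random() < 0.3:
            toks = vocab[rng.choice(profile.vocab_size, size=50, p=bg_p)]
            note_adm.append(admission_ids[i])
            note_role.append("nurse")
            note_ts.append(start - rng.uniform(29.0, 60.0) * DAY)
            note_text.append(" ".join(toks))

    notes = pd.DataFrame(
        {
            "admission_id": note_adm,
            "author_role": note_role,
            "timestamp": pd.to_datetime(note_ts).round("min"),
            "text": note_text,
        }
    )

    # --- incidents ----------------------------------------------------------
    inc_adm: list[str] = []
    inc_time: list[pd.Timestamp] = []
    inc_cat: list[str] = []

    pos_idx = np.flatnonzero(outcome == 1)
    mu_extra = max(profile.incidents_per_positive - 1.0, 0.0)

    # every positive admission gets one qualifying incident in (24 h, 28 d]
    for i in pos_idx:
        t = rng.uniform(1.0, min(28.0, los[i]))
        inc_adm.append(admission_ids[i])
        inc_time.append(starts[i] + t * DAY)
        inc_cat.append(VIOLENT_CATEGORIES[rng.integers(2)])

    # extra violent incidents on positive admissions, windowed so that the
    # overall timing fractions land on the configured targets despite the
    # forced index incidents (q = expected forced share of violent incidents)
    p24, p4w = profile.frac_incidents_first24h, profile.frac_incidents_first4w
    q = 1.0 / (1.0 + mu_extra) if mu_extra > 0 else 1.0
    if mu_extra > 0:
        m = np.array([p24 / (1 - q), (p4w - q) / (1 - q) - p24 / (1 - q), (1 - p4w) / (1 - q)])
        m = np.clip(m, 0.0, None)
        m = m / m.sum()
        n_extra = rng.poisson(mu_extra * len(pos_idx))
        long_pos = pos_idx[los[pos_idx] > 28.0]
        for _ in range(n_extra):
            w = rng.choice(3, p=m)
            if w == 2 and len(long_pos) == 0:
                w = 1
            if w == 0:
                i = pos_idx[rng.integers(len(pos_idx))]
                t = rng.uniform(0.0, min(1.0, los[i]))
            elif w == 1:
                i = pos_idx[rng.integers(len(pos_idx))]
                t = rng.uniform(1.0, min(28.0, los[i]))
            else:
                i = long_pos[rng.integers(len(long_pos))]
                t = rng.uniform(28.0, los[i])
            inc_adm.append(admission_ids[i])
            inc_time.append(starts[i] + t * DAY)
            inc_cat.append(VIOLENT_CATEGORIES[rng.integers(2)])

    # non-violent incidents (never affect the label) on any admission
    n_nv = rng.poisson(profile.nonviolent_incident_rate * n_adm)
    mw = np.array([p24, p4w - p24, 1.0 - p4w])
    mw = mw / mw.sum()
    long_any = np.flatnonzero(los > 28.0)
    mid_any = np.flatnonzero(los > 1.2)
    for _ in range(n_nv):
        w = rng.choice(3, p=mw)
        if w == 2 and len(long_any) == 0:
            w = 1
        if w == 1 and len(mid_any) == 0:
            w = 0
        if w == 0:
            i = rng.integers(n_adm)
            t = rng.uniform(0.0, min(1.0, los[i]))
        elif w == 1:
            i = mid_any[rng.integers(len(mid_any))]
            t = rng.uniform(1.0, min(28.0, los[i]))
        else:
            i = long_any[rng.integers(len(long_any))]
            t = rng.uniform(28.0, los[i])
        inc_adm.append(admission_ids[i])
        inc_time.append(starts[i] + t * DAY)
        inc_cat.append(NONVIOLENT_CATEGORIES[rng.integers(4)])

    n_inc = len(inc_adm)
    soas = np.clip(
        np.round(rng.triangular(1, profile.soas_mode, 22, n_inc)).astype(int), 1, 22
    ) if n_inc else np.array([], dtype=int)
    incidents = pd.DataFrame(
        {
            "admission_id": inc_adm,
            "timestamp": pd.to_datetime(inc_time).round("min") if n_inc else pd.to_datetime([]),
            "category": inc_cat,
            "soas_r": soas,
        }
    ).sort_values(["admission_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    truth = GroundTruth(
        outcome=dict(zip(admission_ids.tolist(), outcome.tolist())),
        latent_risk=dict(zip(admission_ids.tolist(), latent.tolist())),
        signal_terms=list(profile.signal_terms),
    )
    return SiteCorpus(admissions, notes, incidents, truth, profile, seed)


def _shift_inventory(
    base: list[tuple[str, float]], site_shift: float, site_id: str, rng: np.random.Generator
) -> list[tuple[str, float]]:
    out = []
    for term, delta in base:
        if rng.random() < site_shift:
            out.append((f"{term}_{site_id}", delta))
        else:
            out.append((term, delta))
    return out


def generate_pair(
    profile_a: SiteProfile, profile_b: SiteProfile, seed: int
) -> tuple[SiteCorpus, SiteCorpus]:
    """Generate two sites sharing background vocabulary but with partially
    disjoint signal-term inventories.

    ``profile_a.signal_terms`` defines the shared base inventory; both
    profiles must list the same term names. Each site independently replaces
    each base term with a site-local synonym (``term_<site_id>``) with
    probability equal to its own ``site_shift``.
    """
    names_a = [t for t, _ in profile_a.signal_terms]
    names_b = [t for t, _ in profile_b.signal_terms]
    if names_a != names_b:
        raise ValueError("profiles must share the same base signal-term names")
    rng = np.random.default_rng(seed)
    inv_a = _shift_inventory(profile_a.signal_terms, profile_a.site_shift, profile_a.site_id, rng)
    inv_b = _shift_inventory(profile_b.signal_terms, profile_b.site_shift, profile_b.site_id, rng)
    seed_a = int(rng.integers(2**31 - 1))
    seed_b = int(rng.integers(2**31 - 1))
    corpus_a = generate_site(replace(profile_a, signal_terms=inv_a), seed_a)
    corpus_b = generate_site(replace(profile_b, signal_terms=inv_b), seed_b)
    return corpus_a, corpus_b


# --- default Table-1-style site parameterizations ---------------------------

_DIAG_SITE1 = {
    "anxiety": 2.9, "bipolar": 2.0, "cognitive": 0.6, "depressive": 3.3,
    "developmental": 5.6, "eating": 1.8, "mood": 18.2, "personality": 6.7,
    "substance": 3.1, "psychotic": 27.0, "none": 24.9, "other": 3.8,
}
_DIAG_SITE2 = {
    "anxiety": 1.9, "bipolar": 5.2, "cognitive": 3.4, "depressive": 4.6,
    "developmental": 0.9, "eating": 0.3, "mood": 0.3, "personality": 3.6,
    "substance": 11.5, "psychotic": 21.1, "none": 42.8, "other": 4.5,
}

DEFAULT_SIGNAL_TERMS: list[tuple[str, float]] = [
    ("aggressive", 1.4),
    ("angry", 1.3),
    ("threatening", 1.3),
    ("agitation", 1.2),
    ("emergency_medication", 1.2),
    ("seclusion", 1.1),
    ("irritated", 1.1),
    ("shouting", 1.0),
    ("restless", 0.9),
    ("refuses", 0.9),
    ("voluntary", -0.8),
    ("dejected", -0.9),
]


def _normalize(mix: dict[str, float]) -> dict[str, float]:
    s = sum(mix.values())
    return {k: v / s for k, v in mix.items()}


def site_profile_1(**overrides) -> SiteProfile:
    """Site-1-like profile: ~3189 admissions of 2209 patients, 9.1% prevalence,
    length of stay median 16 d (IQR 6-41), predictor-window notes median 2091
    words (IQR 1541-2981), 68.4% / 9.4% of incidents in first 4 wk / 24 h."""
    p = SiteProfile(
        site_id="s1",
        n_patients=2209,
        admission_rate=3189 / 2209,
        prevalence=0.091,
        los_log_mean=float(np.log(16.0)),
        los_log_sd=1.425,
        notelen_log_mean=float(np.log(2091.0)),
        notelen_log_sd=0.489,
        frac_incidents_first4w=0.684,
        frac_incidents_first24h=0.094,
        diagnosis_mixture=_normalize(_DIAG_SITE1),
        vocab_size=5000,
        signal_terms=list(DEFAULT_SIGNAL_TERMS),
        site_shift=0.35,
        incidents_per_positive=962 / 290,
        soas_mode=12,
    )
    return replace(p, **overrides) if overrides else p


def site_profile_2(**overrides) -> SiteProfile:
    """Site-2-like profile: ~3253 admissions of 1919 patients, 7.7% prevalence,
    length of stay median 15 d (IQR 5-40.5), notes median 1961 words (IQR
    1160-3060), 48.8% / 6.4% of incidents in first 4 wk / 24 h."""
    p = SiteProfile(
        site_id="s2",
        n_patients=1919,
        admission_rate=3253 / 1919,
        prevalence=0.077,
        los_log_mean=float(np.log(15.0)),
        los_log_sd=1.551,
        notelen_log_mean=float(np.log(1961.0)),
        notelen_log_sd=0.719,
        frac_incidents_first4w=0.488,
        frac_incidents_first24h=0.064,
        diagnosis_mixture=_normalize(_DIAG_SITE2),
        vocab_size=5000,
        signal_terms=list(DEFAULT_SIGNAL_TERMS),
        site_shift=0.35,
        incidents_per_positive=652 / 247,
        soas_mode=11,
    )
    return replace(p, **overrides) if overrides else p


def desk_profile_1(**overrides) -> SiteProfile:
    """Desk-scale variant of :func:`site_profile_1` (~700 admissions, ~150-word
    synthetic documents, 800-term vocabulary) for demonstrations, continuous
    testing and the reproduction script. All headline rates (prevalence,
    length-of-stay shape, incident timing) keep their full-scale values."""
    base: dict = dict(
        n_patients=480,
        notelen_log_mean=float(np.log(150.0)),
        notelen_log_sd=0.45,
        vocab_size=800,
    )
    base.update(overrides)
    return site_profile_1(**base)


def desk_profile_2(**overrides) -> SiteProfile:
    """Desk-scale variant of :func:`site_profile_2`; see :func:`desk_profile_1`."""
    base: dict = dict(
        n_patients=480,
        notelen_log_mean=float(np.log(150.0)),
        notelen_log_sd=0.45,
        vocab_size=800,
    )
    base.update(overrides)
    return site_profile_2(**base)


# --- I/O ---------------------------------------------------------------------

def write_corpus(corpus: SiteCorpus, outdir: str | Path) -> Path:
    """Write admissions/notes/incidents/truth CSVs plus a JSON provenance
    sidecar (full profile and seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus.admissions.to_csv(outdir / "admissions.csv", index=False)
    corpus.notes.to_csv(outdir / "notes.csv", index=False)
    corpus.incidents.to_csv(outdir / "incidents.csv", index=False)
    corpus.truth.frame().to_csv(outdir / "truth.csv", index=False)
    sidecar = {"profile": asdict(corpus.profile), "seed": corpus.seed}
    (outdir / "profile.json").write_text(json.dumps(sidecar, indent=2, default=list))
    return outdir


def read_corpus(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the three raw tables back (admissions, notes, incidents)."""
    indir = Path(indir)
    admissions = pd.read_csv(indir / "admissions.csv", parse_dates=["start", "end"])
    notes = pd.read_csv(indir / "notes.csv", parse_dates=["timestamp"])
    incidents = pd.read_csv(indir / "incidents.csv", parse_dates=["timestamp"])
    return admissions, notes, incidents
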