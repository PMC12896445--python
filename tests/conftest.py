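import numpy as np
import pytest

from bedsweep import CohortRecord, SyntheticConfig, generate_cohort
from bedsweep.radiobiology import TreatmentScheme, compute_bed


def make_record(
    n_fractions,
    dose_per_fraction,
    event,
    *,
    idx=0,
    age=60.0,
    time=365.0,
    ptv=8.0,
):
    """Minimal valid cohort record with a given scheme and outcome."""
    return CohortRecord(
        patient_id=f"P{idx:03d}",
        tumor_id=f"T{idx:03d}",
        age_years=age,
        sex="female",
        location="convexity",
        gtv_cc=ptv * 0.85,
        ptv_cc=ptv,
        bmi=24.0,
        n_fractions=n_fractions,
        dose_per_fraction_gy=dose_per_fraction,
        ptbe_event=event,
        time_to_event_days=time,
        hypertension=0,
        diabetes=0,
    )


@pytest.fixture
def default_cohort():
    """Default synthetic registry-like cohort (n = 67), fixed seed."""
    return generate_cohort(SyntheticConfig(), seed=11)


@pytest.fixture
def crossing_cohort():
    """Hand-constructed cohort whose outcome is perfectly separated by BED
    only when alpha/beta = 14 (on the integer 2-20 grid).

    Schemes were chosen so the BED ordering of the four tumors crosses just
    below and just above 14: the positives' BED(14) values (41.2 and 41.5 Gy)
    exceed the negatives' (41.05 and 41.0 Gy), while at 13 and 15 a negative
    overtakes a positive.  Each scheme is replicated four times.
    """
    specs = [
        (1, 18.0195, 1),  # BED(14) = 41.2
        (8, 4.0300, 1),  # BED(14) ~ 41.5
        (5, 5.8050, 0),  # BED(14) ~ 41.05
        (1, 17.9603, 0),  # BED(14) ~ 41.0
    ]
    records = []
    for rep in range(4):
        for k, (n, d, ev) in enumerate(specs):
            records.append(
                make_record(
                    n,
                    d,
                    ev,
                    idx=rep * len(specs) + k,
                    age=50.0 + 3 * k + rep,
                    time=200.0 + 40 * k + rep,
                )
            )
    return records


def partial_loglik_1d(beta, time, event, x):
    """Explicit Cox log partial likelihood for one covariate, Breslow ties.

    Independent oracle used to brute-force the maximizer.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for u in np.unique(time[event == 1]):
        risk = time >= u
        dead = (time == u) & (event == 1)
        ll += beta * x[dead].sum() - dead.sum() * np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def concordance_auc(scores, labels):
    """Pairwise Mann-Whitney concordance with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
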