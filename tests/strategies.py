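"""Hypothesis strategies shared across the suite."""

import hypothesis.strategies as st

from yearscxr import CxrFinding, PatientRecord

findings = st.sampled_from(list(CxrFinding))


@st.composite
def patient_records(draw, missing_cxr=False):
    ctpa = draw(st.booleans())
    pe = ctpa and draw(st.booleans())
    if missing_cxr:
        cxr = draw(st.none() | findings)
    else:
        cxr = draw(findings)
    return PatientRecord(
        patient_id=f"p{draw(st.integers(0, 10**6))}",
        years_items=draw(st.integers(0, 3)),
        ddimer_ng_ml=draw(
            st.floats(0, 50_000, allow_nan=False, allow_infinity=False)
        ),
        cxr=cxr,
        pe_confirmed=pe,
        ctpa_indicated=ctpa,
    )


def cohorts(min_size=0, max_size=30, missing_cxr=False):
    return st.lists(
        patient_records(missing_cxr=missing_cxr),
        min_size=min_size,
        max_size=max_size,
    )
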