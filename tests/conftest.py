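import pytest

from bpvalidate.workflow import (
    DeviceReading,
    DeviceStatus,
    MeasurementRound,
    NurseReading,
    PairedMeasurement,
)


def make_round(
    subject_id="S1",
    round_index=1,
    n1=(120.0, 80.0),
    n2=(120.0, 80.0),
    device=(118.0, 79.0),
    status=DeviceStatus.OK,
):
    """Terse round constructor for workflow tests."""
    if status is not DeviceStatus.OK:
        dev = DeviceReading(status=status)
    else:
        dev = DeviceReading(status=DeviceStatus.OK, sbp=device[0], dbp=device[1])
    return MeasurementRound(
        subject_id=subject_id,
        round_index=round_index,
        nurse1=NurseReading(n1[0], n1[1], "nurse1"),
        nurse2=NurseReading(n2[0], n2[1], "nurse2"),
        device=dev,
    )


def pairs_to_rounds(pairs):
    """Re-express retained pairs as rounds (both nurses at the reference)."""
    return [
        MeasurementRound(
            subject_id=p.subject_id,
            round_index=p.round_index,
            nurse1=NurseReading(p.reference_sbp, p.reference_dbp, "nurse1"),
            nurse2=NurseReading(p.reference_sbp, p.reference_dbp, "nurse2"),
            device=DeviceReading(
                status=DeviceStatus.OK, sbp=p.device_sbp, dbp=p.device_dbp
            ),
        )
        for p in pairs
    ]


def make_pair(subject_id="S1", round_index=1, ref=(120.0, 80.0), dev=(120.0, 80.0)):
    return PairedMeasurement(
        subject_id=subject_id,
        round_index=round_index,
        reference_sbp=ref[0],
        reference_dbp=ref[1],
        device_sbp=dev[0],
        device_dbp=dev[1],
    )


@pytest.fixture
def quiet_study():
    """Small noiseless study: device ≡ truth, no failures, no disagreement."""
    from bpvalidate.synthetic import GeneratorConfig, generate_study

    config = GeneratorConfig(
        n_subjects=8,
        observer_error_sd=0.0,
        inter_nurse_extra_sd=0.0,
        device_bias=0.0,
        device_between_subject_sd=0.0,
        device_within_subject_sd=0.0,
        calibration_anchor_weight=0.0,
        failure_probability=0.0,
        reading_gradation=0.0,
        device_resolution=0.0,
        seed=7,
    )
    return generate_study(config)
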