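import numpy as np
import pytest

from ctquant.datamodel import AssayPanel, CtMeasurement, SampleRecord


@pytest.fixture
def small_panel():
    return AssayPanel(targets=("GBAtv1",), references=("ACTB",))


@pytest.fixture
def dual_panel():
    return AssayPanel(targets=("GBAtv1",), references=("ACTB", "PBGD"))


def make_sample(sample_id, group="PD", tissue="blood", **kw):
    defaults = dict(
        subject_id=sample_id,
        cohort_arm="blood" if tissue == "blood" else "brain",
        tissue=tissue,
        group=group,
        age_years=70.0,
    )
    if group != "CTRL":
        defaults.update(age_at_onset_years=65.0, disease_duration_years=5.0)
    defaults.update(kw)
    return SampleRecord(sample_id=sample_id, **defaults)


def make_ct(sample_id, assay, ct, run_id="run1", replicate=1):
    return CtMeasurement(
        sample_id=sample_id, assay=assay, run_id=run_id,
        replicate_index=replicate, ct=ct,
    )


def noiseless_dataset(case_dct_offsets, ctrl_dct_offsets, panel,
                      group="PD", tissue="blood", baseline=24.0, ref_ct=20.0):
    """Exact dataset: each sample's target Ct = baseline + its dCt offset,
    every reference Ct = ref_ct, single run, two identical replicates."""
    samples, cts = [], []

    def add(sample_id, grp, offset):
        samples.append(make_sample(sample_id, group=grp, tissue=tissue))
        for assay in panel.assays:
            ct = ref_ct if assay in panel.references else baseline + offset
            for rep in (1, 2):
                cts.append(make_ct(sample_id, assay, ct, replicate=rep))

    for i, off in enumerate(case_dct_offsets):
        add(f"case{i}", group, off)
    for i, off in enumerate(ctrl_dct_offsets):
        add(f"ctrl{i}", "CTRL", off)
    return samples, cts


def brute_force_point_estimates(samples, measurements, panel, control_group="CTRL"):
    """Independent re-computation of the pipeline's point estimates using
    explicit loops over the definitional formulas (oracle)."""
    # mean Ct per sample x assay: mean of run means over detected wells
    wells = {}
    for m in measurements:
        if m.ct is not None:
            wells.setdefault((m.sample_id, m.assay), {}).setdefault(
                m.run_id, []
            ).append(m.ct)
    mean_ct = {}
    for key, runs in wells.items():
        run_means = [sum(v) / len(v) for v in runs.values()]
        mean_ct[key] = sum(run_means) / len(run_means)

    by_tissue_group = {}
    for s in samples:
        by_tissue_group.setdefault((s.tissue, s.group), []).append(s.sample_id)

    out = {}
    tissues = sorted({s.tissue for s in samples})
    for tissue in tissues:
        ctrl_ids = by_tissue_group.get((tissue, control_group), [])
        groups = sorted(
            g for (t, g) in by_tissue_group if t == tissue and g != control_group
        )
        for group in groups:
            case_ids = by_tissue_group[(tissue, group)]
            for target in panel.targets:
                per_ref_points = []
                for ref in panel.references:
                    case_dcts = [
                        mean_ct[(sid, target)] - mean_ct[(sid, ref)]
                        for sid in case_ids
                        if (sid, target) in mean_ct and (sid, ref) in mean_ct
                    ]
                    ctrl_dcts = [
                        mean_ct[(sid, target)] - mean_ct[(sid, ref)]
                        for sid in ctrl_ids
                        if (sid, target) in mean_ct and (sid, ref) in mean_ct
                    ]
                    ddct = (sum(case_dcts) / len(case_dcts)
                            - sum(ctrl_dcts) / len(ctrl_dcts))
                    per_ref_points.append(2.0 ** -ddct)
                out[(group, tissue, target)] = (
                    sum(per_ref_points) / len(per_ref_points)
                )
    return out


def random_ct_dataset(rng, panel, n_case=5, n_ctrl=5, n_runs=2, n_reps=2,
                      group="PD", tissue="blood"):
    """Arbitrary (not model-based) random Ct table for oracle-equivalence."""
    samples, cts = [], []
    for i in range(n_case + n_ctrl):
        grp = group if i < n_case else "CTRL"
        sid = f"s{i}"
        samples.append(make_sample(sid, group=grp, tissue=tissue))
        for assay in panel.assays:
            for r in range(n_runs):
                for k in range(n_reps):
                    cts.append(make_ct(
                        sid, assay, float(rng.uniform(15, 35)),
                        run_id=f"run{r + 1}", replicate=k + 1,
                    ))
    return samples, cts
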