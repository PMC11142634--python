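import numpy as np
import pytest
from hypothesis import settings

from crossfc.atlas import AtlasModel, default_atlas
from crossfc.core import CohortStack, Connectome, SubjectRecord, devectorize
from crossfc.simulate import SimulationDesign, SiteParams, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desikan():
    return default_atlas()


def make_toy_atlas(n_regions=8, seed=0, networks=("default-mode", "visual")):
    """Small atlas with two ICNs and mirrored hemispheres."""
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    tags = []
    for k in range(n_regions):
        tags.append(networks[k % len(networks)])
    return AtlasModel(
        region_labels=tuple(f"r{i}" for i in range(n_regions)),
        hemisphere=tuple(["L"] * half + ["R"] * (n_regions - half)),
        centroid_mm=rng.uniform(-70, 70, (n_regions, 3)),
        icn_assignment=tuple(tags),
    )


@pytest.fixture
def toy_atlas():
    return make_toy_atlas()


def make_null_stack(n_per_group, n_regions, seed, groups=("control", "rTLE"),
                    bands=("alpha",), clinical=True):
    """Exchangeable cohort: all groups drawn from one distribution."""
    rng = np.random.default_rng(seed)
    e = n_regions * (n_regions - 1) // 2
    subs = []
    for grp in groups:
        for i in range(n_per_group):
            patient = grp != "control"
            rec = SubjectRecord(
                subject_id=f"{grp}-{i}",
                group=grp,
                age=float(rng.uniform(20, 60)),
                sex="F" if rng.random() < 0.5 else "M",
                site="site256" if rng.random() < 0.5 else "site64",
                epilepsy_duration=float(rng.uniform(1, 30)) if patient and clinical else None,
                is_hs=bool(rng.random() < 0.5) if patient and clinical else None,
                ied_per_min=float(rng.exponential(0.3)) if patient and clinical else None,
            )
            fm = np.tanh(0.3 + 0.3 * rng.standard_normal(e))
            rec.connectomes[("fmri", "none")] = Connectome(
                devectorize(fm, n_regions), "fmri", "none", rec.subject_id
            )
            for band in bands:
                ee = 1.0 / (1.0 + np.exp(-(-1.6 + 0.5 * rng.standard_normal(e))))
                rec.connectomes[("eeg", band)] = Connectome(
                    devectorize(ee, n_regions), "eeg", band, rec.subject_id
                )
            subs.append(rec)
    return CohortStack(subs)


def study_like_design(seed, n=(17, 17, 16)):
    """Default coupling targets at the reference cohort sizes."""
    n_ctl, n_rtle, n_ltle = n
    return SimulationDesign(
        group_sizes={
            "control": {"site256": n_ctl - n_ctl // 2, "site64": n_ctl // 2},
            "rTLE": {"site256": n_rtle - n_rtle // 2, "site64": n_rtle // 2},
            "lTLE": {"site256": n_ltle - n_ltle // 2, "site64": n_ltle // 2},
        },
        seed=seed,
    )


def small_site(tr_s=2.0, n_volumes=40, eeg_fs=1000.0, n_segments=40):
    return {"site256": SiteParams(tr_s=tr_s, n_volumes=n_volumes,
                                  eeg_fs=eeg_fs, n_segments=n_segments)}


@pytest.fixture(scope="session")
def planted_stack(desikan):
    """One cohort at the default design (17/17/16), used by several tests."""
    stack, gt = generate_cohort(study_like_design(101), desikan)
    return stack, gt
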