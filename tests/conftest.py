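import pandas as pd
import pytest

from trd_episodes import (
    RunConfig,
    Scenario,
    generate_cohort,
    run_pipeline,
)
from trd_episodes.simulate import write_scenario_outputs


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic mid-sized synthetic cohort plus ground truth."""
    sc = Scenario(n_patients=400, seed=11)
    return generate_cohort(sc)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_cohort):
    """Full pipeline run over the small cohort; yields (dir, manifest)."""
    ds, truth = small_cohort
    base = tmp_path_factory.mktemp("run")
    write_scenario_outputs(ds, truth, base / "in")
    cfg = RunConfig(input_dir=str(base / "in"), out_dir=str(base / "out"))
    manifest = run_pipeline(cfg)
    return base, manifest


def pipeline_frames(ds):
    """Run the in-memory stages over a dataset; returns a dict of frames
    and objects (cohort, episodes, regimens, lots, assessments)."""
    from trd_episodes import cohort as C
    from trd_episodes import episodes as E
    from trd_episodes import regimens as R
    from trd_episodes import trd as T

    cohort_df, cascade = C.select_cohort(ds)
    eps = E.build_all_episodes(ds, cohort_df)
    regs = R.build_all_regimens(ds, eps)
    assessments = T.label_episodes(eps, regs)
    lots = {k: R.derive_lots(v) for k, v in regs.items()}
    return {
        "cohort": cohort_df,
        "cascade": cascade,
        "episodes": eps,
        "episodes_df": E.episodes_frame(eps),
        "regimens": regs,
        "regimens_df": R.regimens_frame(regs),
        "lots": lots,
        "lots_df": R.lots_frame(lots),
        "assessments": assessments,
    }
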