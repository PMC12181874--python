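import pandas as pd
import pytest

from faersig.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small deterministic corpus with duplicates and planted signals."""
    return generate(SyntheticConfig(n_cases=3000, seed=7))


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_dataset):
    outdir = tmp_path_factory.mktemp("synth")
    small_dataset.write(outdir)
    return outdir


def make_demo(rows):
    """DEMO frame from (primaryid, caseid, fda_dt_yyyymmdd) triples."""
    return pd.DataFrame([
        {"primaryid": str(pid), "caseid": str(cid),
         "fda_dt": pd.Timestamp(str(dt)), "fda_dt_prec": "day",
         "event_dt": pd.NaT, "event_dt_prec": None, "sex": "UNK",
         "age_years": float("nan"), "occp_cod": None,
         "reporter_country": "Not Specified"}
        for pid, cid, dt in rows])
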