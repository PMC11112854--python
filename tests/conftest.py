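import numpy as np
import pandas as pd
import pytest

from lik.design import ExperimentDesign, Sample, default_design
from lik.io import ProteinGroupTable


@pytest.fixture
def small_design() -> ExperimentDesign:
    """Compact 3-arm design: 3 native pulldowns (distinct probes), 1 UV and
    1 formaldehyde pulldown, each with a paired control."""
    samples = []
    for probe in ("P1", "P2", "P3"):
        cid = f"n_{probe}_c"
        samples.append(Sample(cid, "native", probe, "control",
                              "nonhomologous_probe", ""))
        samples.append(Sample(f"n_{probe}", "native", probe, "pulldown",
                              "not_applicable", cid))
    samples.append(Sample("uv_c", "uv", "", "control", "no_probe", ""))
    samples.append(Sample("uv_p", "uv", "pooled", "pulldown", "not_applicable", "uv_c"))
    samples.append(Sample("fa_c", "formaldehyde", "", "control", "scrambled", ""))
    samples.append(Sample("fa_p", "formaldehyde", "pooled", "pulldown",
                          "not_applicable", "fa_c"))
    return ExperimentDesign(samples, probe_panel=("P1", "P2", "P3"))


@pytest.fixture
def full_design() -> ExperimentDesign:
    return default_design()


def make_table(design: ExperimentDesign, intensities: dict[str, list[float]],
               unique_peptides: list[int] | None = None,
               contaminant: list[bool] | None = None) -> ProteinGroupTable:
    """Build a ProteinGroupTable from a dict of per-sample intensity lists."""
    n = len(next(iter(intensities.values())))
    ids = [f"PG{i:03d}" for i in range(n)]
    meta = pd.DataFrame(index=pd.Index(ids, name="protein_group_id"))
    meta["gene_id"] = [f"G{i:03d}" for i in range(n)]
    meta["unique_peptides"] = unique_peptides if unique_peptides is not None else 5
    meta["is_contaminant"] = contaminant if contaminant is not None else False
    meta["is_decoy"] = False
    inten = pd.DataFrame({s: np.asarray(v, dtype=float)
                          for s, v in intensities.items()}, index=meta.index)
    return ProteinGroupTable(meta, inten)
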