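import warnings

import numpy as np
import pytest

import knobscan as ks
from knobscan.phenotypes import blues_frame


@pytest.fixture(scope="session")
def default_panel():
    """One default assay-1 panel with phenotypes, BLUEs and entry types."""
    params = ks.GeneratorParams(seed=7)
    panel = ks.generate_panel(params)
    records = ks.simulate_phenotypes(panel, params)
    blues = blues_frame(records, [e.entry_id for e in panel])
    entry_types = {e.entry_id: e.entry_type for e in panel}
    return params, panel, records, blues, entry_types


@pytest.fixture(scope="session")
def recovery_simulations():
    """200 default assay-1 panels: K9S female-flowering effect estimates under
    both encodings plus entry-mean heritability estimates per panel.

    Shared by the parameter-recovery checks; seeds 1..200 are the package's
    reference replication set.
    """
    eff_add, eff_dom, h2_mf, h2_gs = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(1, 201):
            params = ks.GeneratorParams(seed=seed)
            panel = ks.generate_panel(params)
            records = ks.simulate_phenotypes(panel, params)
            blues = blues_frame(records, [e.entry_id for e in panel])
            entry_types = {e.entry_id: e.entry_type for e in panel}
            h2_mf.append(ks.estimate_heritability(records, "mf", entry_types)[0])
            h2_gs.append(ks.estimate_heritability(records, "gs", entry_types)[0])
            for encoding, sink in (("additive", eff_add), ("dominance", eff_dom)):
                spec = ks.AssociationModelSpec(encoding=encoding)
                res = ks.run_scan(panel, blues["ff"], spec, trait="ff")
                row = res[res.locus_id == "K9S"]
                if len(row):
                    sink.append(float(row.effect.iloc[0]))
    return {
        "effect_additive_ff": np.array(eff_add),
        "effect_dominance_ff": np.array(eff_dom),
        "h2_mf": np.array(h2_mf),
        "h2_gs": np.array(h2_gs),
    }
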