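"""End-to-end run of the three-part analysis on a planted-signal cohort.

Used for power/recovery studies: generate a smoker cohort where one cis SNP
drives an ARE gene and status follows a logistic model on that expression,
then run GSEA (SNC vs SC), the cis-eQTL scan, the logistic expression-status
scan and the genotype-status Fisher test, and integrate the three axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import CisEqtl
from .enrichment import Gsea
from .integrate import (ExpressionStatus, build_integration_report,
                        genotype_status_fisher)
from .simulate import IntegrationSim, simulate_integration_dataset

__all__ = ["PlantedRun", "run_planted_pipeline"]


@dataclass
class PlantedRun:
    sim: IntegrationSim
    gsea_table: pd.DataFrame
    top_set: str
    eqtl_table: pd.DataFrame
    report: pd.DataFrame
    causal_tier: float

    @property
    def set_ranked_first(self) -> bool:
        return self.top_set == self.sim.are_set_name

    @property
    def causal_in_tier1(self) -> bool:
        return self.causal_tier == 1


def run_planted_pipeline(seed: int, nperm_gsea: int = 200,
                         nperm_eqtl: int = 1000,
                         nperm_logit: int = 500) -> PlantedRun:
    """Run the full pipeline on one planted-signal cohort.

    Returns the GSEA ranking, the eQTL table and the integration report with
    the causal pair's tier.  Raises nothing on a degenerate status draw with
    fewer than 3 samples in a group (possible but rare); the caller sees the
    exception from the model constructors in that case.
    """
    sim = simulate_integration_dataset(seed=seed)
    status = sim.status

    # GSEA with SNC as group A so positive NES means "up in non-cancer"
    gsea = Gsea(sim.expr, status.to_numpy(), sim.gene_sets, group_a="SNC")
    gres = gsea.fit(nperm=nperm_gsea, seed=seed + 1)

    eres = CisEqtl(sim.expr, sim.geno, sim.regions).fit(nperm=nperm_eqtl,
                                                        seed=seed + 2)

    are_probes = [g for g in sim.expr.probes
                  if g in sim.gene_sets[0].genes]
    sres = ExpressionStatus(sim.expr.subset_probes(are_probes), status) \
        .fit(nperm=nperm_logit, seed=seed + 3)

    d = sim.geno.dosage.loc[sim.causal_snp]
    case = (status == "SC").to_numpy()
    _, p_gp = genotype_status_fisher(d, status)
    geno_pheno = pd.DataFrame({
        "snp": [sim.causal_snp],
        "p": [p_gp],
        "maf_case": [float(d[case].mean() / 2)],
        "maf_control": [float(d[~case].mean() / 2)],
    })
    pheno = sres.table.reset_index(names="probe")[["probe", "beta", "p_corrected"]]
    report = build_integration_report(eres.table, pheno, geno_pheno)
    row = report[(report["snp"] == sim.causal_snp)
                 & (report["probe"] == sim.causal_gene)]
    tier = float(row["tier"].iloc[0]) if len(row) and pd.notna(row["tier"].iloc[0]) \
        else float("nan")
    return PlantedRun(sim, gres.table, gres.top(), eres.table, report, tier)
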