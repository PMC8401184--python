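# The 24 shipped contrast specifications, in three groups by the data
# layers they combine.  Layer names refer to direction-resolved gene sets
# materialized by the pipeline:
#   DM_WGBS_hyper / DM_WGBS_hypo    WGBS DM genes (hyper/hypo in resistance)
#   DE_array_down / DE_array_up     cell-line expression array (R vs S)
#   reexpressed_RT                  re-expressed after reactivation treatment
#   TCGA_DE_down / TCGA_DE_up       cohort DE under the approach-1 selection
#   DE_cohort_down / DE_cohort_up   cohort RNA-seq DE under approach-2 selection
#   DM_450K_hyper / DM_450K_hypo    beta-matrix DM genes (tumor vs control)
#
# Group 1: WGBS + expression array + cohort (approach 1)
- {name: g1_hyper_inhibited,            group: group1, layers: [DM_WGBS_hyper, DE_array_down]}
- {name: g1_hyper_inhibited_cohort,     group: group1, layers: [DM_WGBS_hyper, DE_array_down, TCGA_DE_down]}
- {name: g1_hypo_overexpressed,         group: group1, layers: [DM_WGBS_hypo, DE_array_up]}
- {name: g1_hypo_overexpressed_cohort,  group: group1, layers: [DM_WGBS_hypo, DE_array_up, TCGA_DE_up]}
# Group 2: 450K beta matrix + cohort RNA-seq + approach-1 cohort
- {name: g2_hyper_inhibited,            group: group2, layers: [DM_450K_hyper, DE_cohort_down]}
- {name: g2_hyper_inhibited_cohort,     group: group2, layers: [DM_450K_hyper, DE_cohort_down, TCGA_DE_down]}
- {name: g2_hypo_overexpressed,         group: group2, layers: [DM_450K_hypo, DE_cohort_up]}
- {name: g2_hypo_overexpressed_cohort,  group: group2, layers: [DM_450K_hypo, DE_cohort_up, TCGA_DE_up]}
- {name: g2_hyper_cohort,               group: group2, layers: [DM_450K_hyper, TCGA_DE_down]}
- {name: g2_hypo_cohort,                group: group2, layers: [DM_450K_hypo, TCGA_DE_up]}
- {name: g2_expr_concordant_down,       group: group2, layers: [DE_cohort_down, TCGA_DE_down]}
- {name: g2_expr_concordant_up,         group: group2, layers: [DE_cohort_up, TCGA_DE_up]}
# Group 3: WGBS + expression array + 450K + cohort RNA-seq
- {name: g3_hyper_all_meth,             group: group3, layers: [DM_WGBS_hyper, DM_450K_hyper]}
- {name: g3_hyper_meth_expr,            group: group3, layers: [DM_WGBS_hyper, DE_array_down, DM_450K_hyper]}
- {name: g3_hyper_meth_rnaseq,          group: group3, layers: [DM_WGBS_hyper, DE_array_down, DE_cohort_down]}
- {name: g3_hyper_quad,                 group: group3, layers: [DM_WGBS_hyper, DE_array_down, DM_450K_hyper, DE_cohort_down]}
- {name: g3_hyper_wgbs_rnaseq,          group: group3, layers: [DM_WGBS_hyper, DE_cohort_down]}
- {name: g3_array_450k_down,            group: group3, layers: [DE_array_down, DM_450K_hyper]}
- {name: g3_hypo_all_meth,              group: group3, layers: [DM_WGBS_hypo, DM_450K_hypo]}
- {name: g3_hypo_meth_expr,             group: group3, layers: [DM_WGBS_hypo, DE_array_up, DM_450K_hypo]}
- {name: g3_hypo_meth_rnaseq,           group: group3, layers: [DM_WGBS_hypo, DE_array_up, DE_cohort_up]}
- {name: g3_hypo_quad,                  group: group3, layers: [DM_WGBS_hypo, DE_array_up, DM_450K_hypo, DE_cohort_up]}
- {name: g3_hypo_wgbs_rnaseq,           group: group3, layers: [DM_WGBS_hypo, DE_cohort_up]}
- {name: g3_array_450k_up,              group: group3, layers: [DE_array_up, DM_450K_hypo]}
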