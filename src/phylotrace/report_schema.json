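{
  "$comment": "Minimal structural schema for phylotrace JSON reports, version 1.0. Validated by phylotrace.schema.validate_report.",
  "schema_version": "1.0",
  "analyze": {
    "required": ["schema_version", "inputs", "n_samples", "burnin", "parameters", "trees", "converged"],
    "burnin": {"required": ["mode", "samples"]},
    "parameter": {"required": ["summary", "diagnostics"]},
    "summary": {
      "required": ["name", "n_used", "mean", "std_dev", "minimum", "maximum", "ci_lower", "ci_upper", "ess", "rel_uncertainty_pct"]
    },
    "diagnostics": {
      "required": ["parameter", "geweke_z", "psrf", "burnin_geweke", "burnin_ess", "burnin_suggested", "ess_at_suggested", "converged", "thresholds"]
    },
    "tree": {"required": ["n_total", "n_unique", "entries", "consensus"]},
    "tree_entry": {"required": ["newick", "count", "probability"]}
  },
  "compare": {
    "required": ["schema_version", "inputs", "burnin", "mann_whitney", "split_chisq", "joint_summary"],
    "two_sample": {"required": ["statistic", "p_value", "method", "n1", "n2"]}
  }
}
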