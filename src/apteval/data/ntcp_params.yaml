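# LKB NTCP parameter table: editable, clearly-labelled literature stand-in
# defaults for the four head-and-neck endpoints evaluated by the adaptation
# study.  Each row names the LKB model family its values are drawn from;
# replace with institution-specific fits before any clinical use.
endpoints:
  larynx_edema:
    structure: larynx
    n: 0.45
    m: 0.27
    td50_gy: 46.3
    source: "LKB fit family for >= grade 2 laryngeal edema (Rancati-type); configurable stand-in default"
  dysphagia:
    structure: constrictors
    n: 1.0
    m: 0.32
    td50_gy: 51.0
    source: "mean-dose LKB family for >= grade 2 dysphagia (pharyngeal constrictors); configurable stand-in default"
  xerostomia:
    structure: parotid
    n: 1.0
    m: 0.40
    td50_gy: 28.4
    source: "mean-dose LKB family for severe xerostomia (parotid); configurable stand-in default"
  esophagitis:
    structure: esophagus
    n: 1.0
    m: 0.36
    td50_gy: 47.0
    source: "mean-dose LKB family for >= grade 2 acute esophagitis; configurable stand-in default"
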