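{
  "_comment": "Algorithm keyword <-> KiSAO id mapping used when writing/reading SED-ML. The variable-step parameter id below is the 'adaptive time steps' family entry; no normative id exists for flagging variable-step output, so it is recorded here and can be overridden by passing a custom mapping to the SED-ML writer/reader.",
  "algorithms": {
    "lsoda": "KISAO:0000088",
    "cvode": "KISAO:0000019",
    "gillespie": "KISAO:0000029",
    "rk4": "KISAO:0000032"
  },
  "parameters": {
    "relative_tolerance": "KISAO:0000209",
    "absolute_tolerance": "KISAO:0000211",
    "seed": "KISAO:0000488",
    "variable_step_size": "KISAO:0000107"
  }
}
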