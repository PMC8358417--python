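{
  "platinum monotherapy (carboplatin or cisplatin)": "platinum monotherapy",
  "paclitaxel/platinum-based chemotherapy": "carboplatin/paclitaxel",
  "carboplatin/paclitaxel (conventional)": "carboplatin/paclitaxel",
  "chemotherapy (pld, paclitaxel or topotecan)": "chemotherapy",
  "bevacizumab/chemotherapy (pld, paclitaxel or topotecan)": "chemotherapy/bevacizumab",
  "topotecan/placebo": "topotecan",
  "toptecan/placebo": "topotecan",
  "gemcitabine/placebo": "gemcitabine",
  "pegylated liposomal doxorubicin": "pld",
  "liposomal doxorubicin": "pld",
  "carboplatin/paclitaxel followed by no further treatment": "carboplatin/paclitaxel, no maintenance",
  "olaparib during carboplatin/paclitaxel followed by olaparib maintenance": "carboplatin/paclitaxel/olaparib, then olaparib maintenance"
}
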