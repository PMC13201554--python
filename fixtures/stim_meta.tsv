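unit	group	donor
D01_ctrl	ctrl	D01
D01_insulin	insulin	D01
D02_ctrl	ctrl	D02
D02_insulin	insulin	D02
D03_ctrl	ctrl	D03
D03_insulin	insulin	D03
D04_ctrl	ctrl	D04
D04_insulin	insulin	D04
D05_ctrl	ctrl	D05
D05_insulin	insulin	D05
D06_ctrl	ctrl	D06
D06_insulin	insulin	D06
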