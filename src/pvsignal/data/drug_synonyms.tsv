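alias	canonical
nexavar	sorafenib
sutent	sunitinib
caprelsa	vandetanib
zactima	vandetanib
cabometyx	cabozantinib
cometriq	cabozantinib
lenvima	lenvatinib
kisplyx	lenvatinib
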