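species	group	population	region
Liposcelis brunnea	IA	L. brunnea_P-CZ	Prague, Czech Republic
Liposcelis brunnea	IA	L. brunnea_USA	USA
Liposcelis entomophila	IA	L. entomophila_BJ-P. R. China	Beijing, China
Liposcelis entomophila	IA	L. entomophila_HBWH-P. R. China	Wuhan, Hubei Province, China
Liposcelis entomophila	IA	L. entomophila_P-CZ	Prague, Czech Republic
Liposcelis entomophila	IA	L. entomophila_CQ-P. R. China	Chongqing, China
Liposcelis decolor	IB	L. decolor_CQ-P. R. China	Chongqing, China
Liposcelis decolor	IB	L. decolor_P-CZ	Prague, Czech Republic
Liposcelis decolor	IB	L. decolor_USA	USA
Liposcelis pearmani	IB	L. pearmani_USA	USA
Liposcelis rufa	IB	L. rufa_USA	USA
Liposcelis mendax	IIC	L. mendax_JS-P. R. China	Jiangsu Province, China
Liposcelis bostrychophila	IID	L. bostrychophila_BJ-P. R. China	Beijing, China
Liposcelis bostrychophila	IID	L. bostrychophila_GX-P. R. China	Guangxi, China
Liposcelis bostrychophila	IID	L. bostrychophila_CQ-P. R. China	Chongqing, China
Liposcelis bostrychophila	IID	L. bostrychophila_P-CZ	Prague, Czech Republic
Liposcelis bostrychophila	IID	L. bostrychophila_USA	Manhattan, USA
Liposcelis corrodens	IID	L. corrodens_P-CZ	Prague, Czech Republic
Liposcelis corrodens	IID	L. corrodens_USA	USA
Liposcelis paeta	IID	L. paeta_USA	USA
Liposcelis paeta	IID	L. paeta_HBSJZ-P. R. China	Shijiazhuang, Hebei Province, China
Liposcelis paeta	IID	L. paeta_ZJ-P. R. China	Zhejiang Province, China
Liposcelis paeta	IID	L. paeta_HBWH-P. R. China	Wuhan, Hubei Province, China
Liposcelis paeta	IID	L. paeta_P-CZ	Prague, Czech Republic
Liposcelis tricolor	IID	L. tricolor_SD-P. R. China	Heze, Shandong Province, China
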