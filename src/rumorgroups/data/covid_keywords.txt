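指揮中心
奎寧
急性呼吸道感染
新型病毒
疫情
口罩
負壓
抗疫
陽性
新型冠狀病毒
潛伏期
李文亮
纖維化
自主管理
群聚
隔離
確診
武漢
譚德塞
陰性
新冠
染疫
武肺
封城
肺炎
自主健康管理
防疫
冠狀
家庭感染
covid
ibuprofen
2019-ncov
coronavirus
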