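# Default mainland-usage phrase list (editable). A message containing any of
# these phrases — in either script — is flagged as probable China origin even
# when written entirely in traditional characters, because the vocabulary
# itself is mainland usage (Taiwan uses a different word for the same thing).
# One phrase per line; '#' lines are ignored.
視頻
视频
信息
軟件
软件
網絡
网络
質量
打印
硬盤
硬盘
鼠標
鼠标
屏幕
激光
數碼
数码
出租車
出租车
公交車
公交车
土豆
西紅柿
西红柿
酸奶
立馬
立马
靠譜
靠谱
大陸防疫專家
内地
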