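# Simplified-only characters with their traditional counterparts.
# Column 1: simplified form (a codepoint that is NOT itself a traditional
# character); column 2: the traditional form. Characters whose simplified and
# traditional forms coincide, or whose simplified form doubles as a distinct
# traditional character (e.g. 表/里/后/干/面), are deliberately excluded.
爱	愛
罢	罷
办	辦
帮	幫
宝	寶
报	報
贝	貝
备	備
笔	筆
币	幣
毕	畢
边	邊
变	變
标	標
别	別
宾	賓
驳	駁
补	補
财	財
参	參
残	殘
仓	倉
苍	蒼
产	產
长	長
尝	嘗
车	車
彻	徹
尘	塵
陈	陳
称	稱
惩	懲
迟	遲
齿	齒
冲	衝
虫	蟲
筹	籌
处	處
传	傳
疮	瘡
词	詞
从	從
聪	聰
达	達
带	帶
单	單
担	擔
弹	彈
当	當
党	黨
导	導
岛	島
盗	盜
灯	燈
邓	鄧
敌	敵
递	遞
点	點
电	電
钓	釣
顶	頂
订	訂
东	東
动	動
冻	凍
栋	棟
独	獨
读	讀
断	斷
对	對
队	隊
夺	奪
鹅	鵝
恶	惡
儿	兒
尔	爾
发	發
罚	罰
阀	閥
烦	煩
访	訪
纺	紡
飞	飛
费	費
纷	紛
坟	墳
奋	奮
愤	憤
丰	豐
风	風
冯	馮
缝	縫
凤	鳳
肤	膚
负	負
妇	婦
复	復
该	該
盖	蓋
赶	趕
钢	鋼
岗	崗
个	個
给	給
沟	溝
构	構
购	購
顾	顧
关	關
观	觀
馆	館
广	廣
规	規
归	歸
龟	龜
轨	軌
贵	貴
滚	滾
锅	鍋
国	國
过	過
汉	漢
号	號
轰	轟
红	紅
华	華
画	畫
话	話
怀	懷
欢	歡
环	環
还	還
换	換
黄	黃
会	會
汇	匯
货	貨
获	獲
机	機
积	積
鸡	雞
极	極
级	級
挤	擠
计	計
记	記
际	際
继	繼
纪	紀
夹	夾
价	價
驾	駕
歼	殲
监	監
坚	堅
间	間
检	檢
减	減
简	簡
见	見
键	鍵
舰	艦
将	將
奖	獎
讲	講
酱	醬
胶	膠
阶	階
节	節
杰	傑
洁	潔
结	結
紧	緊
进	進
晋	晉
经	經
惊	驚
镜	鏡
旧	舊
剧	劇
据	據
举	舉
军	軍
开	開
课	課
垦	墾
恳	懇
库	庫
裤	褲
块	塊
宽	寬
矿	礦
亏	虧
扩	擴
蜡	蠟
兰	蘭
拦	攔
烂	爛
劳	勞
乐	樂
类	類
离	離
礼	禮
丽	麗
历	歷
励	勵
连	連
联	聯
恋	戀
练	練
粮	糧
两	兩
辆	輛
疗	療
辽	遼
临	臨
邻	鄰
灵	靈
龄	齡
刘	劉
龙	龍
楼	樓
炉	爐
陆	陸
录	錄
虑	慮
绿	綠
乱	亂
论	論
罗	羅
骡	騾
骆	駱
妈	媽
马	馬
吗	嗎
买	買
卖	賣
麦	麥
满	滿
猫	貓
贸	貿
么	麼
没	沒
门	門
们	們
梦	夢
谜	謎
弥	彌
觅	覓
庙	廟
灭	滅
鸣	鳴
谬	謬
亩	畝
难	難
脑	腦
恼	惱
内	內
拟	擬
酿	釀
鸟	鳥
聂	聶
宁	寧
农	農
浓	濃
诺	諾
欧	歐
殴	毆
盘	盤
赔	賠
喷	噴
鹏	鵬
骗	騙
频	頻
贫	貧
苹	蘋
凭	憑
评	評
泼	潑
扑	撲
铺	鋪
朴	樸
谱	譜
齐	齊
骑	騎
岂	豈
启	啟
气	氣
弃	棄
牵	牽
铅	鉛
迁	遷
签	簽
谦	謙
钱	錢
钳	鉗
枪	槍
墙	牆
桥	橋
侨	僑
窍	竅
亲	親
轻	輕
倾	傾
顷	頃
请	請
庆	慶
穷	窮
琼	瓊
区	區
驱	驅
权	權
劝	勸
确	確
让	讓
扰	擾
热	熱
认	認
荣	榮
软	軟
锐	銳
润	潤
洒	灑
伞	傘
丧	喪
扫	掃
涩	澀
杀	殺
纱	紗
筛	篩
晒	曬
闪	閃
陕	陝
赡	贍
伤	傷
赏	賞
烧	燒
绍	紹
设	設
摄	攝
绳	繩
胜	勝
圣	聖
师	師
狮	獅
湿	濕
诗	詩
时	時
实	實
识	識
驶	駛
势	勢
适	適
释	釋
视	視
试	試
寿	壽
兽	獸
书	書
术	術
树	樹
输	輸
属	屬
数	數
帅	帥
双	雙
谁	誰
顺	順
说	說
硕	碩
丝	絲
饲	飼
耸	聳
苏	蘇
诉	訴
肃	肅
虽	雖
随	隨
岁	歲
孙	孫
损	損
缩	縮
锁	鎖
态	態
摊	攤
贪	貪
瘫	癱
谈	談
叹	嘆
汤	湯
烫	燙
涛	濤
讨	討
腾	騰
体	體
条	條
贴	貼
铁	鐵
厅	廳
听	聽
铜	銅
统	統
头	頭
图	圖
涂	塗
团	團
驼	駝
袜	襪
弯	彎
湾	灣
顽	頑
万	萬
网	網
为	為
伟	偉
违	違
围	圍
维	維
卫	衛
谓	謂
温	溫
闻	聞
稳	穩
问	問
乌	烏
诬	誣
无	無
吴	吳
务	務
误	誤
锡	錫
牺	犧
习	習
戏	戲
细	細
虾	蝦
吓	嚇
鲜	鮮
纤	纖
显	顯
险	險
现	現
献	獻
县	縣
宪	憲
线	線
乡	鄉
详	詳
响	響
项	項
萧	蕭
销	銷
晓	曉
协	協
挟	挾
写	寫
泻	瀉
谢	謝
兴	興
汹	洶
锈	鏽
许	許
绪	緒
续	續
轩	軒
悬	懸
选	選
学	學
寻	尋
训	訓
讯	訊
逊	遜
压	壓
鸦	鴉
亚	亞
严	嚴
盐	鹽
颜	顏
阎	閻
艳	豔
验	驗
阳	陽
养	養
样	樣
药	藥
钥	鑰
爷	爺
页	頁
业	業
叶	葉
医	醫
仪	儀
遗	遺
亿	億
忆	憶
义	義
议	議
艺	藝
异	異
译	譯
阴	陰
银	銀
饮	飲
隐	隱
应	應
营	營
蝇	蠅
赢	贏
忧	憂
优	優
邮	郵
犹	猶
诱	誘
鱼	魚
渔	漁
与	與
屿	嶼
语	語
狱	獄
誉	譽
预	預
园	園
员	員
圆	圓
缘	緣
远	遠
愿	願
约	約
跃	躍
运	運
杂	雜
灾	災
载	載
赞	贊
脏	臟
凿	鑿
枣	棗
责	責
择	擇
泽	澤
贼	賊
赠	贈
轧	軋
闸	閘
诈	詐
斋	齋
债	債
战	戰
张	張
涨	漲
帐	帳
账	賬
赵	趙
这	這
贞	貞
针	針
侦	偵
诊	診
阵	陣
镇	鎮
争	爭
郑	鄭
证	證
织	織
职	職
执	執
纸	紙
质	質
钟	鐘
肿	腫
种	種
众	眾
轴	軸
昼	晝
皱	皺
骤	驟
猪	豬
诸	諸
烛	燭
嘱	囑
贮	貯
铸	鑄
筑	築
庄	莊
装	裝
壮	壯
状	狀
锥	錐
坠	墜
浊	濁
资	資
渍	漬
踪	蹤
综	綜
总	總
纵	縱
邹	鄒
组	組
钻	鑽
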