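# Default Chinese stop-word list (traditional and simplified forms).
# One token per line; lines starting with '#' are ignored. Edit freely.
的
了
是
在
我
你
他
她
它
我們
你們
他們
我们
你们
他们
有
和
就
不
人
都
一
一個
一个
上
也
很
到
說
说
要
去
會
会
著
着
沒有
没有
看
好
自己
這
这
那
嗎
吗
呢
吧
啊
被
讓
让
把
給
给
但
而
與
与
或
於
于
及
以
之
其
為
为
所
因為
因为
所以
如果
雖然
虽然
但是
可是
還
还
再
又
才
只
個
从
從
對
对
能
可以
可能
應該
应该
這個
这个
那個
那个
什麼
什么
怎麼
怎么
這樣
这样
那樣
那样
已經
已经
曾經
曾经
一些
一樣
一样
大家
非常
真的
如此
而且
並且
并且
然後
然后
因此
即使
只是
就是
還是
还是
或者
以及
例如
比如
等等
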