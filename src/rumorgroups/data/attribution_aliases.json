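{
  "Zhong Nan-Shan": ["鍾南山", "鐘南山", "钟南山"],
  "Chen Shih-Chung": ["陳時中", "陈时中", "衛福部長", "卫福部长"],
  "Taiwan Medical Association": ["醫師全聯會", "医师全联会", "醫師公會全國聯合會"],
  "CECC": ["指揮中心", "指挥中心", "疫情指揮中心"],
  "WHO": ["世衛", "世卫", "世界衛生組織", "世界卫生组织", "WHO", "譚德塞", "谭德塞"]
}
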